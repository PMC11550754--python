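"""Peer-based lack-of-output decomposition for personalized targets.

For an inefficient DMU the optimal lambda weights identify a composite
benchmark on the frontier: the lambda-weighted mix of its peers.  Per
output, the shortfall ("lack of output") is

    lack_r = (sum over peers j of lambda_j * y_rj) - y_r,own

i.e. the composite value minus the unit's own value.  Back-transforming
own + lack through the recorded preprocessing transform expresses the
shortfall on the original per-mille / diversity scale, which is what a
personalized recommendation ("increase Lactobacillus by ...") needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dea import DEAResult, PEER_LAMBDA_TOL
from .preprocess import TransformRecord

__all__ = [
    "LackReport",
    "weighted_peer_outputs",
    "composite_outputs",
    "lack_of_output",
    "render_lack_report",
]

LACK_NEGATIVE_TOL = 1e-7


@dataclass
class LackReport:
    dmu_id: object
    output_names: list[str]
    peer_ids: list
    peer_lambdas: np.ndarray  # (n_peer,)
    peer_outputs: np.ndarray  # (n_peer, n_out) raw values
    weighted: np.ndarray  # (n_peer, n_out) lambda-weighted values
    composite: np.ndarray  # (n_out,)
    own: np.ndarray  # (n_out,)
    lack: np.ndarray  # (n_out,)
    back_transformed_lack: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "dmu_id": self.dmu_id,
            "outputs": self.output_names,
            "peers": [
                {
                    "id": pid,
                    "lambda": float(lam),
                    "outputs": [float(v) for v in row],
                    "weighted": [float(v) for v in wrow],
                }
                for pid, lam, row, wrow in zip(
                    self.peer_ids, self.peer_lambdas, self.peer_outputs, self.weighted
                )
            ],
            "composite": [float(v) for v in self.composite],
            "own": [float(v) for v in self.own],
            "lack": [float(v) for v in self.lack],
        }
        if self.back_transformed_lack is not None:
            d["back_transformed_lack"] = [float(v) for v in self.back_transformed_lack]
        return d

    def to_text(self) -> str:
        """Fixed-width table: peers, weighted values, sums, lack row."""
        names = self.output_names
        width = max(12, max(len(n) for n in names) + 2)
        head = " " * 26 + "".join(f"{n:>{width}}" for n in names)
        lines = [head]
        for pid, lam, row, wrow in zip(
            self.peer_ids, self.peer_lambdas, self.peer_outputs, self.weighted
        ):
            lines.append(
                f"Peer {str(pid):<12}λ={lam:6.3f} " + "".join(f"{v:>{width}.3f}" for v in row)
            )
            lines.append(" " * 8 + f"{'weighted':<18}" + "".join(f"{v:>{width}.3f}" for v in wrow))
        lines.append(f"{'Sum of weighted values':<26}" + "".join(f"{v:>{width}.3f}" for v in self.composite))
        lines.append(f"{'Own values':<26}" + "".join(f"{v:>{width}.3f}" for v in self.own))
        lines.append(f"{'Lack of output':<26}" + "".join(f"{v:>{width}.3f}" for v in self.lack))
        if self.back_transformed_lack is not None:
            lines.append(
                f"{'Back-transformed lack':<26}"
                + "".join(f"{v:>{width}.3f}" for v in self.back_transformed_lack)
            )
        return "\n".join(lines)


def weighted_peer_outputs(
    result: DEAResult, Y: np.ndarray, lambda_tol: float = 1e-3
) -> np.ndarray:
    """Per-peer lambda-weighted output matrix w_jr = lambda_j * y_rj.

    The VRS convexity condition sum(lambda) = 1 is enforced to
    ``lambda_tol``; the default admits weights quoted to a few decimals
    while still rejecting a lambda/Y mismatch.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    lam = np.asarray(result.lam, dtype=float)
    if lam.shape[0] != Y.shape[0]:
        raise ValueError("lambda vector does not match the output matrix")
    if abs(lam.sum() - 1.0) > lambda_tol:
        raise ValueError(f"VRS lambda must sum to 1 (got {lam.sum():.8f})")
    peer_idx = np.nonzero(lam > PEER_LAMBDA_TOL)[0]
    return lam[peer_idx, None] * Y[peer_idx, :]


def composite_outputs(weighted: np.ndarray) -> np.ndarray:
    """Column sums of the weighted peer matrix: the composite benchmark."""
    weighted = np.atleast_2d(np.asarray(weighted, dtype=float))
    return weighted.sum(axis=0)


def lack_of_output(composite: np.ndarray, own_outputs: np.ndarray) -> np.ndarray:
    """Elementwise composite - own; materially negative lack flags a mismatch."""
    composite = np.asarray(composite, dtype=float)
    own = np.asarray(own_outputs, dtype=float)
    if composite.shape != own.shape:
        raise ValueError("composite and own output vectors must align")
    lack = composite - own
    if np.any(lack < -LACK_NEGATIVE_TOL):
        raise ValueError(
            "negative lack of output beyond solver tolerance; lambda weights "
            "and output matrix do not belong to the same solved problem"
        )
    return lack


def render_lack_report(
    result: DEAResult,
    Y: np.ndarray,
    output_names: list[str] | None = None,
    transform_records: list[TransformRecord] | None = None,
    own_index: int | None = None,
) -> LackReport:
    """Assemble the full per-DMU report, with back-transformed lack when
    transform records for the output columns are available.

    The back-transformed lack is inverse(own + lack) - inverse(own) on the
    original measurement scale; for efficient DMUs every entry is zero.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    lam = np.asarray(result.lam, dtype=float)
    if own_index is None:
        own_index = list(range(Y.shape[0])).index(result.dmu_id) if isinstance(result.dmu_id, (int, np.integer)) else None
    if own_index is None:
        raise ValueError("own_index required when dmu ids are not positional")
    own = Y[own_index, :]
    if output_names is None:
        output_names = [f"output_{r}" for r in range(Y.shape[1])]
    if result.efficient:
        # the unit is its own benchmark: zero lack by definition
        weighted = np.atleast_2d(own.copy())
        peer_idx = np.array([own_index])
        comp = own.copy()
        lack = np.zeros_like(own)
    else:
        weighted = weighted_peer_outputs(result, Y)
        peer_idx = np.nonzero(lam > PEER_LAMBDA_TOL)[0]
        comp = composite_outputs(weighted)
        lack = lack_of_output(comp, own)
    back = None
    if transform_records is not None:
        by_name = {r.variable: r for r in transform_records}
        missing = [n for n in output_names if n not in by_name]
        if missing:
            warnings.warn(
                f"no transform record for outputs {missing}; report emitted "
                "without the back-transformed row"
            )
        else:
            recs = [by_name[n] for n in output_names]
            back = np.array(
                [
                    float(rec.inverse(o + l) - rec.inverse(o))
                    for rec, o, l in zip(recs, own, lack)
                ]
            )
    return LackReport(
        dmu_id=result.dmu_id,
        output_names=list(output_names),
        peer_ids=[result.dmu_id] if result.efficient else list(result.peers),
        peer_lambdas=lam[peer_idx] if not result.efficient else np.array([1.0]),
        peer_outputs=Y[peer_idx, :],
        weighted=weighted,
        composite=comp,
        own=own,
        lack=np.maximum(lack, 0.0),
        back_transformed_lack=back,
    )
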