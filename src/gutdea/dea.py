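"""Output-oriented data envelopment analysis (BCC / variable returns to scale).

Each participant is a decision-making unit (DMU) converting lifestyle
inputs into beneficial-microbiota outputs.  For DMU *o* the model finds
the largest uniform output expansion phi feasible inside the convex hull
of observed practice:

    max  phi
    s.t. sum_j lambda_j x_ij <= x_io          for every input i
         sum_j lambda_j y_rj >= phi * y_ro    for every output r
         sum_j lambda_j = 1                   (VRS; dropped under CRS)
         lambda_j >= 0

phi >= 1 is the Farrell output expansion ("inefficiency score"); the
efficiency score is its reciprocal 1/phi in (0, 1].  Frontier DMUs with
positive lambda in the optimum are the unit's peers.  The linear programs
are solved with the HiGHS solver; a dense grid search over the
lambda-simplex serves as an independent oracle on tiny problems.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = ["DEAProblem", "DEAResult", "solve_output_bcc", "solve_all", "brute_force_phi"]

PEER_LAMBDA_TOL = 1e-6
EFFICIENT_TOL = 1e-7
FEASIBILITY_SLACK = 1e-9


@dataclass(frozen=True)
class DEAProblem:
    """Strictly positive input/output matrices over n_dmu units."""

    X: np.ndarray  # (n_dmu, n_in)
    Y: np.ndarray  # (n_dmu, n_out)
    dmu_ids: tuple = ()
    rts: str = "vrs"  # vrs | crs

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if X.shape[0] != Y.shape[0] or X.shape[0] < 1:
            raise ValueError("X and Y must have the same positive number of rows")
        if np.any(~np.isfinite(X)) or np.any(~np.isfinite(Y)):
            raise ValueError("X and Y must be finite")
        if np.any(X <= 0) or np.any(Y <= 0):
            raise ValueError("DEA requires strictly positive inputs and outputs")
        if self.rts not in ("vrs", "crs"):
            raise ValueError("rts must be 'vrs' or 'crs'")
        if not self.dmu_ids:
            object.__setattr__(self, "dmu_ids", tuple(range(X.shape[0])))
        elif len(self.dmu_ids) != X.shape[0]:
            raise ValueError("dmu_ids length mismatch")

    @property
    def n_dmu(self) -> int:
        return self.X.shape[0]


@dataclass
class DEAResult:
    dmu_id: object
    phi: float  # Farrell output expansion >= 1
    score: float  # 1 / phi in (0, 1]
    lam: np.ndarray  # weights over all DMUs
    peers: list  # dmu ids with lambda above tolerance
    status: str = "optimal"

    @property
    def efficient(self) -> bool:
        return self.score >= 1.0 - EFFICIENT_TOL


def solve_output_bcc(problem: DEAProblem, dmu_index: int) -> DEAResult:
    """Solve the output-oriented envelopment LP for one DMU."""
    n, n_in = problem.X.shape
    n_out = problem.Y.shape[1]
    if not 0 <= dmu_index < n:
        raise IndexError(f"dmu_index {dmu_index} out of range [0, {n})")
    x_o = problem.X[dmu_index]
    y_o = problem.Y[dmu_index]
    # decision vector: [phi, lambda_1 .. lambda_n]
    c = np.zeros(n + 1)
    c[0] = -1.0  # maximize phi
    A_ub = np.zeros((n_in + n_out, n + 1))
    b_ub = np.zeros(n_in + n_out)
    A_ub[:n_in, 1:] = problem.X.T  # sum_j lam_j x_ij <= x_io
    b_ub[:n_in] = x_o
    A_ub[n_in:, 0] = y_o  # phi y_ro - sum_j lam_j y_rj <= 0
    A_ub[n_in:, 1:] = -problem.Y.T
    if problem.rts == "vrs":
        A_eq = np.zeros((1, n + 1))
        A_eq[0, 1:] = 1.0
        b_eq = np.array([1.0])
    else:
        A_eq = b_eq = None
    bounds = [(0.0, None)] * (n + 1)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(
            f"DEA LP failed for DMU {problem.dmu_ids[dmu_index]!r}: {res.message} "
            "(valid positive data cannot be infeasible under VRS; check the inputs)"
        )
    phi = float(res.x[0])
    lam = np.maximum(res.x[1:], 0.0)
    # tiny numerical undershoot of the self-feasible phi=1 solution
    phi = max(phi, 1.0)
    peers = [problem.dmu_ids[j] for j in np.nonzero(lam > PEER_LAMBDA_TOL)[0]]
    return DEAResult(problem.dmu_ids[dmu_index], phi, 1.0 / phi, lam, peers)


def solve_all(problem: DEAProblem) -> list[DEAResult]:
    """Efficiency of every DMU, with per-unit failures carrying the DMU id."""
    return [solve_output_bcc(problem, j) for j in range(problem.n_dmu)]


def summarize(results: list[DEAResult]) -> dict:
    scores = np.array([r.score for r in results])
    return {
        "n_dmu": len(results),
        "mean_score": float(scores.mean()),
        "min_score": float(scores.min()),
        "n_efficient": int(sum(r.efficient for r in results)),
        "fraction_efficient": float(np.mean([r.efficient for r in results])),
    }


@functools.lru_cache(maxsize=8)
def _simplex_grid(n: int, steps: int) -> np.ndarray:
    """All lambda vectors on the n-simplex with entries k/steps."""
    if n == 1:
        return np.ones((1, 1))
    # stars and bars over the compositions of `steps` into n parts
    combos = itertools.combinations(range(steps + n - 1), n - 1)
    bars = np.fromiter(
        (b for combo in combos for b in combo), dtype=np.int64
    ).reshape(-1, n - 1)
    full = np.empty((bars.shape[0], n + 1), dtype=np.int64)
    full[:, 0] = -1
    full[:, 1:-1] = bars
    full[:, -1] = steps + n - 1
    counts = np.diff(full, axis=1) - 1
    return counts / steps


def brute_force_phi(problem: DEAProblem, dmu_index: int, grid_resolution: float = 0.01) -> float:
    """Independent grid-search oracle for the output expansion phi.

    Enumerates lambda on a dense simplex grid, keeps the input-feasible
    points and maximizes min_r (sum_j lam_j y_rj) / y_ro over them.  Only
    meant for tiny problems (n_dmu <= 6); accuracy is limited by the grid
    step, so compare against the LP with a tolerance of a couple of steps.
    """
    n = problem.n_dmu
    if n > 6:
        raise ValueError("brute-force oracle is restricted to n_dmu <= 6")
    steps = int(round(1.0 / grid_resolution))
    if steps < 2:
        raise ValueError("grid too coarse; decrease grid_resolution")
    if problem.rts != "vrs":
        raise ValueError("grid oracle implemented for VRS only")
    lam = _simplex_grid(n, steps)
    x_o = problem.X[dmu_index]
    y_o = problem.Y[dmu_index]
    feasible = np.all(lam @ problem.X <= x_o + FEASIBILITY_SLACK, axis=1)
    lam = lam[feasible]
    if lam.shape[0] == 0:
        # the unit itself is always feasible; only possible on a grid that
        # cannot represent the unit vector, which steps >= 2 always can
        raise RuntimeError("no feasible grid point; grid too coarse")
    phi_candidates = np.min((lam @ problem.Y) / y_o, axis=1)
    return float(phi_candidates.max())
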