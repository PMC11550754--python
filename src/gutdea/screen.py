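"""Correlation-based screening of candidate DEA inputs and outputs.

Before building the frontier, every candidate lifestyle input is tested
for Pearson correlation against every candidate microbiota output.  An
input with no evidence of association with any output contributes nothing
to the efficiency comparison and is dropped; a *beneficial* output whose
significant associations with the inputs run in the wrong (negative)
direction violates the model's "more input, more output" semantics and is
dropped too.  The full correlation grid is retained for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationCell", "ScreeningDecision", "pearson_with_ci", "screen_variables"]


@dataclass(frozen=True)
class CorrelationCell:
    input: str
    output: str
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@dataclass
class ScreeningDecision:
    kept_inputs: list[str]
    kept_outputs: list[str]
    excluded: dict[str, str]  # variable -> reason
    grid: list[CorrelationCell] = field(default_factory=list)

    def grid_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.grid])

    def to_dict(self) -> dict:
        return {
            "kept_inputs": self.kept_inputs,
            "kept_outputs": self.kept_outputs,
            "excluded": self.excluded,
        }


def pearson_with_ci(x, y, alpha: float = 0.05, names=("x", "y")) -> CorrelationCell:
    """Pearson r with two-sided t-test p-value and Fisher-z confidence interval.

    The CI is arctanh(r) +/- z_{1-alpha/2} / sqrt(n-3), back-transformed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant column")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = zcrit / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationCell(names[0], names[1], r, float(lo), float(hi), p, n)


def screen_variables(
    inputs_table: pd.DataFrame,
    outputs_table: pd.DataFrame,
    alpha: float = 0.05,
    input_rule: str = "any",
    sign_rule: str = "majority",
) -> ScreeningDecision:
    """Apply the exclusion rules over the full input x output correlation grid.

    input_rule:
        "any" -- keep an input if at least one output correlation has
                 p <= alpha (default); "all" -- keep only if every pair is
                 significant.
    sign_rule (outputs only, applied to the significant pairs):
        "majority" -- exclude a beneficial output when more than half of
                      its significant input correlations are negative
                      (default); "any_negative" -- exclude on a single
                      significant negative pair.
    Outputs with no significant pair at all are excluded for lack of
    correlation evidence, symmetrically with inputs.
    """
    if inputs_table.shape[1] == 0 or outputs_table.shape[1] == 0:
        raise ValueError("need at least one candidate input and one candidate output")
    if input_rule not in ("any", "all"):
        raise ValueError("input_rule must be 'any' or 'all'")
    if sign_rule not in ("majority", "any_negative"):
        raise ValueError("sign_rule must be 'majority' or 'any_negative'")

    grid: list[CorrelationCell] = []
    for inp in inputs_table.columns:
        for out in outputs_table.columns:
            grid.append(
                pearson_with_ci(
                    inputs_table[inp], outputs_table[out], alpha=alpha, names=(inp, out)
                )
            )

    excluded: dict[str, str] = {}
    kept_inputs = []
    for inp in inputs_table.columns:
        cells = [c for c in grid if c.input == inp]
        significant = [c for c in cells if c.p_value <= alpha]
        ok = len(significant) > 0 if input_rule == "any" else len(significant) == len(cells)
        if ok:
            kept_inputs.append(inp)
        else:
            excluded[inp] = "no-significant-correlation"

    kept_outputs = []
    for out in outputs_table.columns:
        cells = [c for c in grid if c.output == out]
        significant = [c for c in cells if c.p_value <= alpha]
        if not significant:
            excluded[out] = "no-significant-correlation"
            continue
        negative = [c for c in significant if c.r < 0]
        wrong_sign = (
            len(negative) * 2 > len(significant)
            if sign_rule == "majority"
            else len(negative) > 0
        )
        if wrong_sign:
            excluded[out] = "wrong-sign"
        else:
            kept_outputs.append(out)

    return ScreeningDecision(kept_inputs, kept_outputs, excluded, grid)
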