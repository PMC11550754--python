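"""Derivation of DEA-ready variables from the raw cohort table.

The frontier model requires strictly positive inputs and outputs, and
"more is better" semantics on both sides.  This module provides the
conversions and transforms that get the cohort there, each recorded so it
can be inverted when personalized targets are reported back on the
original scale:

* unit conversions (sodium -> salt grams, alcohol grams -> units),
* energy adjustment of nutrient intakes by the residual method,
* inversion of detrimental inputs (alcohol, smoking) about a pivot so
  that lower consumption means a larger, healthier input,
* mean imputation of missing sleep at 6.5 h/d,
* a per-column positivity shift for columns containing zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TransformRecord",
    "sodium_to_salt",
    "grams_to_alcohol_units",
    "energy_adjust_residual",
    "invert_detrimental",
    "impute_sleep",
    "make_positive",
    "apply_transform",
    "invert_transform",
    "DEFAULT_PIVOTS",
]

SALT_PER_SODIUM = 2.54  # g salt per g sodium
GRAMS_PER_ALCOHOL_UNIT = 21.0
SLEEP_IMPUTE_HOURS = 6.5
# pivots for detrimental-input inversion: value' = pivot - value
DEFAULT_PIVOTS = {"alcohol_units": 5.5, "cigarettes_per_day": 90.0}


@dataclass(frozen=True)
class TransformRecord:
    """Invertible record of one column transform.

    kind ``inversion`` stores the pivot p (x' = p - x); kind ``shift``
    stores the additive constant delta (x' = x + delta); ``identity``
    stores nothing.  Exactly one record exists per transformed DEA column.
    """

    variable: str
    kind: str  # inversion | shift | identity
    pivot: float | None = None
    delta: float | None = None

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "inversion":
            return self.pivot - x
        if self.kind == "shift":
            return x + self.delta
        return x.copy()

    def inverse(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "inversion":
            return self.pivot - x
        if self.kind == "shift":
            return x - self.delta
        return x.copy()


def apply_transform(record: TransformRecord, x):
    return record.forward(x)


def invert_transform(record: TransformRecord, x):
    return record.inverse(x)


def records_to_json(records: list[TransformRecord]) -> str:
    return json.dumps([asdict(r) for r in records], indent=2)


def records_from_json(text: str) -> list[TransformRecord]:
    return [TransformRecord(**d) for d in json.loads(text)]


def sodium_to_salt(sodium_g_per_day):
    """Salt (g/d) = 2.54 x sodium (g/d)."""
    sodium = np.asarray(sodium_g_per_day, dtype=float)
    if np.any(sodium < 0):
        raise ValueError("sodium intake must be non-negative")
    return SALT_PER_SODIUM * sodium


def grams_to_alcohol_units(grams_per_day):
    """Alcohol units/d, one unit being 21 g pure alcohol."""
    grams = np.asarray(grams_per_day, dtype=float)
    if np.any(grams < 0):
        raise ValueError("alcohol intake must be non-negative")
    return grams / GRAMS_PER_ALCOHOL_UNIT


def energy_adjust_residual(nutrient_column, energy_column):
    """Energy-adjust a nutrient intake by the residual method.

    OLS of nutrient on total energy; the adjusted value is the residual
    plus the predicted intake at the sample-mean energy.  The result is
    uncorrelated with energy and keeps the nutrient's sample mean, i.e.
    it isolates nutrient composition from sheer quantity eaten.
    """
    nutrient = np.asarray(nutrient_column, dtype=float)
    energy = np.asarray(energy_column, dtype=float)
    if nutrient.shape != energy.shape or nutrient.ndim != 1:
        raise ValueError("nutrient and energy must be 1-d arrays of equal length")
    if len(nutrient) < 3:
        raise ValueError("need at least 3 observations")
    energy_c = energy - energy.mean()
    ss_energy = float(energy_c @ energy_c)
    if ss_energy <= 0:
        raise ValueError("energy column has zero variance; residual method undefined")
    slope = float(energy_c @ (nutrient - nutrient.mean())) / ss_energy
    residual = nutrient - nutrient.mean() - slope * energy_c
    return residual + nutrient.mean()  # prediction at mean energy is the mean intake


def invert_detrimental(value, pivot: float):
    """Map a detrimental consumption x to pivot - x so that less is more.

    Values at or above the pivot would produce a non-positive DEA input;
    they are rejected with instructions rather than clamped.
    """
    x = np.asarray(value, dtype=float)
    if np.any(x < 0):
        raise ValueError("consumption must be non-negative")
    if np.any(x >= pivot):
        raise ValueError(
            f"value >= pivot {pivot}: raise the pivot so every inverted "
            "value stays strictly positive"
        )
    return pivot - x


def impute_sleep(column):
    """Replace missing sleep hours with 6.5 h/d (cohort mean and median)."""
    x = np.asarray(column, dtype=float)
    return np.where(np.isnan(x), SLEEP_IMPUTE_HOURS, x)


def make_positive(
    columns: pd.DataFrame,
) -> tuple[pd.DataFrame, list[TransformRecord]]:
    """Shift each column containing zeros so all values are strictly positive.

    For a column with zeros, every value is shifted up by delta = half the
    minimum positive value, so the smallest (zero) entry lands strictly
    below every formerly-positive one and within-column rankings are
    preserved; all-positive columns get an identity record.  The shift is
    recorded and exactly invertible.
    """
    if isinstance(columns, pd.Series):
        columns = columns.to_frame()
    out = columns.copy()
    records: list[TransformRecord] = []
    for name in columns.columns:
        x = columns[name].to_numpy(dtype=float)
        if np.any(np.isnan(x)):
            raise ValueError(f"column {name!r} has missing values")
        if np.any(x < 0):
            raise ValueError(
                f"column {name!r} has negative values; invert detrimental "
                "variables before the positivity transform"
            )
        if np.all(x > 0):
            records.append(TransformRecord(name, "identity"))
            continue
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError(f"column {name!r} is all zeros; no positive scale to set delta")
        delta = float(positive.min()) / 2.0
        rec = TransformRecord(name, "shift", delta=delta)
        out[name] = rec.forward(x)
        records.append(rec)
    return out, records


def preprocess_dea_table(
    table: pd.DataFrame,
    input_columns: list[str],
    output_columns: list[str],
    pivots: dict[str, float] | None = None,
    energy_column: str = "energy_kcal",
    energy_adjust: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, list[TransformRecord]]:
    """Full DEA preprocessing of a cohort table.

    Order of operations per the analysis plan: sleep mean-imputation,
    energy-residual adjustment of nutrient inputs, pivot inversion of
    detrimental inputs, then the positivity shift on every DEA column.
    Returns the transformed (input+output) frame and one TransformRecord
    per column.
    """
    pivots = DEFAULT_PIVOTS if pivots is None else pivots
    work = table.copy()
    if "sleep_h" in work.columns:
        work["sleep_h"] = impute_sleep(work["sleep_h"])
    if energy_adjust is None:
        nutrient_like = ("mufa_g", "n3pufa_g", "n6pufa_g", "fiber_sol_g", "fiber_insol_g")
        energy_adjust = tuple(c for c in nutrient_like if c in input_columns)
    if energy_adjust and energy_column in work.columns:
        for col in energy_adjust:
            work[col] = energy_adjust_residual(work[col], work[energy_column])
    inversion_records: dict[str, TransformRecord] = {}
    for col, pivot in pivots.items():
        if col in input_columns:
            work[col] = invert_detrimental(work[col], pivot)
            inversion_records[col] = TransformRecord(col, "inversion", pivot=pivot)
    dea = work[input_columns + output_columns].copy()
    # the residual method can push a small intake just below zero; shift
    # such a column up to zero first, folding the offset into its record
    pre_shift: dict[str, float] = {}
    for col in dea.columns:
        cmin = float(dea[col].min())
        if cmin < 0:
            pre_shift[col] = -cmin
            dea[col] = dea[col] - cmin
    dea, shift_records = make_positive(dea)
    shift_records = [
        TransformRecord(
            rec.variable,
            "shift",
            delta=pre_shift[rec.variable] + (rec.delta if rec.kind == "shift" else 0.0),
        )
        if rec.variable in pre_shift
        else rec
        for rec in shift_records
    ]
    records: list[TransformRecord] = []
    for rec in shift_records:
        if rec.variable in inversion_records and rec.kind == "identity":
            records.append(inversion_records[rec.variable])
        elif rec.variable in inversion_records:
            # inversion followed by a shift: fold into one affine record
            # x' = (pivot + delta) - x, still kind "inversion"
            records.append(
                TransformRecord(
                    rec.variable,
                    "inversion",
                    pivot=inversion_records[rec.variable].pivot + rec.delta,
                )
            )
        else:
            records.append(rec)
    return dea, records
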