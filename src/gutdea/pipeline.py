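"""End-to-end orchestration: cohort -> preprocess -> screen -> DEA ->
lack decomposition -> Tobit / multiple imputation.

Stages communicate through files in the run directory so any stage can be
re-run alone and the whole run is reproducible from the provenance
manifest (config, seeds, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synth import (
    CohortConfig,
    default_config,
    generate_cohort,
    inject_missingness,
    DEA_INPUT_CANDIDATES,
    DEA_OUTPUT_CANDIDATES,
)
from .preprocess import (
    DEFAULT_PIVOTS,
    energy_adjust_residual,
    impute_sleep,
    preprocess_dea_table,
    records_to_json,
    records_from_json,
)
from .screen import screen_variables
from .dea import DEAProblem, solve_all, summarize
from .decompose import render_lack_report
from .tobit import fit_tobit
from .impute import quickpred, mice_pmm, pool_rubin, rubin_combine, stepwise_backward_mi

__all__ = ["RunConfig", "run_pipeline"]

TOBIT_COVARIATES = [
    "age",
    "sex_female",
    "bmi",
    "egfr",
    "hemoglobin",
    "hba1c",
    "energy_kcal",
    "fat_g",
    "salt_g",
    "ffq_yogurt",
    "ffq_natto",
    "ffq_seaweed",
    "ffq_fried",
    "ffq_coffee",
    "antibiotics",
    "probiotics",
]


@dataclass
class RunConfig:
    outdir: str = "gutdea_run"
    input_csv: str | None = None  # load a cohort instead of synthesizing one
    n: int = 577
    seed: int = 20240927
    pivots: dict = field(default_factory=lambda: dict(DEFAULT_PIVOTS))
    screening_alpha: float = 0.05
    input_rule: str = "any"
    sign_rule: str = "majority"
    rts: str = "vrs"
    tobit_covariates: list = field(default_factory=lambda: list(TOBIT_COVARIATES))
    mi_m: int = 20
    mi_maxit: int = 50
    mi_donors: int = 5
    mi_mincor: float = 0.1
    mi_minpuc: float = 0.25
    stepwise_alpha: float = 0.05
    retain_frac: float = 0.5
    energy_adjust: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_or_synthesize(config: RunConfig, outdir: Path) -> pd.DataFrame:
    if config.input_csv is not None:
        cohort = pd.read_csv(config.input_csv)
    else:
        synth_cfg = default_config()
        synth_cfg.n = config.n
        synth_cfg.seed = config.seed
        cohort = generate_cohort(synth_cfg)
        cohort = inject_missingness(cohort, synth_cfg.missingness, seed=config.seed + 1)
    missing_cols = [
        c
        for c in DEA_INPUT_CANDIDATES + DEA_OUTPUT_CANDIDATES
        if c not in cohort.columns
    ]
    if missing_cols:
        raise ValueError(f"cohort table lacks required DEA columns: {missing_cols}")
    cohort.to_csv(outdir / "cohort.csv", index=False)
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the artifact summary dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # stage 1: cohort
    cohort = _load_or_synthesize(config, outdir)
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")

    # stage 2: benefit-scale derivation (sleep imputation, energy adjustment)
    work = cohort.copy()
    work["sleep_h"] = impute_sleep(work["sleep_h"])
    nutrient_inputs = [
        c
        for c in ("mufa_g", "n3pufa_g", "n6pufa_g", "fiber_sol_g", "fiber_insol_g")
        if c in work.columns
    ]
    if config.energy_adjust:
        for col in nutrient_inputs:
            work[col] = energy_adjust_residual(work[col], work["energy_kcal"])

    # stage 3: correlation screening on the measurement scale, where a
    # beneficial output must correlate positively with a beneficial input
    decision = screen_variables(
        work[DEA_INPUT_CANDIDATES],
        work[DEA_OUTPUT_CANDIDATES],
        alpha=config.screening_alpha,
        input_rule=config.input_rule,
        sign_rule=config.sign_rule,
    )
    decision.grid_frame().to_csv(outdir / "screening_grid.csv", index=False)
    (outdir / "screening_decision.json").write_text(json.dumps(decision.to_dict(), indent=2))
    inputs = decision.kept_inputs
    outputs = decision.kept_outputs
    if not inputs or not outputs:
        raise RuntimeError(
            "screening removed every candidate input or output; nothing to envelop"
        )

    # stage 4: DEA-ready transforms (inversion of detrimental inputs,
    # positivity shift) on the kept columns only
    dea_table, records = preprocess_dea_table(
        work,
        inputs,
        outputs,
        pivots={k: v for k, v in config.pivots.items() if k in inputs},
        energy_adjust=(),  # already applied above
    )
    dea_table.to_csv(outdir / "dea_ready.csv", index=False)
    (outdir / "transforms.json").write_text(records_to_json(records))

    # stage 5: the frontier
    problem = DEAProblem(
        X=dea_table[inputs].to_numpy(),
        Y=dea_table[outputs].to_numpy(),
        rts=config.rts,
    )
    results = solve_all(problem)
    summary = summarize(results)
    scores = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"],
            "phi": [r.phi for r in results],
            "score": [r.score for r in results],
            "efficient": [int(r.efficient) for r in results],
            "peers": [";".join(str(p) for p in r.peers) for r in results],
        }
    )
    scores.to_csv(outdir / "scores.csv", index=False)

    # stage 6: lack decomposition for the most inefficient unit
    worst = int(np.argmin(scores["score"].to_numpy()))
    report = render_lack_report(
        results[worst],
        problem.Y,
        output_names=outputs,
        transform_records=records,
        own_index=worst,
    )
    (outdir / "lack_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (outdir / "lack_report.txt").write_text(report.to_text() + "\n")

    # stage 7: Tobit regression with multiple imputation
    analysis = cohort.copy()
    analysis["sleep_h"] = impute_sleep(analysis["sleep_h"])
    analysis["score"] = scores["score"].to_numpy()
    covariates = [
        c
        for c in config.tobit_covariates
        if c in analysis.columns and analysis[c].nunique(dropna=True) > 1
    ]
    mi_frame = analysis.drop(columns=["participant_id"])
    forced = ["age", "sex_female", "score"] + outputs
    pred_matrix = quickpred(
        mi_frame,
        mincor=config.mi_mincor,
        minpuc=config.mi_minpuc,
        forced=[c for c in forced if c in mi_frame.columns],
    )
    if len(pred_matrix):
        imputations = mice_pmm(
            mi_frame,
            pred_matrix,
            m=config.mi_m,
            maxit=config.mi_maxit,
            donors=config.mi_donors,
            seed=config.seed + 2,
        )
        tables = list(imputations)
    else:
        tables = [mi_frame]
    pred_matrix.to_csv(outdir / "predictor_matrix.csv")

    uni_fits = {
        c: [
            fit_tobit(t["score"].to_numpy(), t[[c]].to_numpy(), names=[c]) for t in tables
        ]
        for c in covariates
    }
    uni_rows = []
    for c, fits in uni_fits.items():
        pooled = pool_rubin(fits)
        frame = pooled.summary_frame(scale=1e3)
        uni_rows.append(
            {
                "variable": c,
                "coefficient_x1e3": frame.loc[c, "coefficient"],
                "se_x1e3": frame.loc[c, "se"],
                "p_value": frame.loc[c, "p_value"],
            }
        )
    uni_table = pd.DataFrame(uni_rows).set_index("variable")
    uni_table.to_csv(outdir / "regression_univariate.csv")

    selection = stepwise_backward_mi(
        tables,
        "score",
        covariates,
        alpha=config.stepwise_alpha,
        retain_frac=config.retain_frac,
    )
    pd.Series(selection.counts, name="selected_in_datasets").to_csv(
        outdir / "selection_counts.csv"
    )
    if selection.pooled is not None:
        multi = selection.pooled.summary_frame(scale=1e3)
        multi.columns = ["coefficient_x1e3", "se_x1e3", "p_value"]
    else:
        multi = pd.DataFrame(columns=["coefficient_x1e3", "se_x1e3", "p_value"])
    multi.to_csv(outdir / "regression_multivariate.csv")
    if selection.mean_vif is not None:
        selection.mean_vif.rename("mean_vif").to_csv(outdir / "vif.csv")

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_participants": n,
        "kept_inputs": inputs,
        "kept_outputs": outputs,
        "excluded": decision.excluded,
        "dea_summary": summary,
        "most_inefficient": {
            "participant_index": worst,
            "score": float(scores["score"].iloc[worst]),
        },
        "mi": {"m": len(tables), "targets": list(pred_matrix.index)},
        "final_model": selection.selected,
        "selection_counts": selection.counts,
        "max_mean_vif": (
            float(selection.mean_vif.max()) if selection.mean_vif is not None else None
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
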