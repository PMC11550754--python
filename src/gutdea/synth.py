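"""Synthetic cohort generation for the gut-microbiota efficiency pipeline.

The real study cohort cannot be shared, so every downstream stage is
exercised on synthetic cohorts that emulate its published structure:

* lifestyle / nutrient intakes as truncated normals with the published
  mean and SD (moment-matched, so the *realized* moments hit the targets
  even when the truncation at zero bites);
* alcohol and cigarette consumption as zero-inflated truncated normals
  (a non-consuming point mass plus a positive consumption distribution);
* genus relative abundances (per mille) as zero-inflated log-normals
  matched to the published nonzero-part median/IQR and nonzero prevalence;
* a Gaussian copula tying everything together, with latent correlations
  calibrated by Gauss-Hermite quadrature so the realized Pearson r between
  a configured pair matches the target on the observed (post-transform)
  scale;
* missing values injected completely at random, with exact per-variable
  counts, into covariates only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats

__all__ = [
    "MarginalSpec",
    "GenusSpec",
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "inject_missingness",
    "DEA_INPUT_CANDIDATES",
    "DEA_OUTPUT_CANDIDATES",
    "DEA_COLUMNS",
]

# Candidate DEA columns. Missingness is never allowed here: the frontier
# model has no notion of a partially observed decision-making unit.
DEA_INPUT_CANDIDATES = [
    "mufa_g",
    "n3pufa_g",
    "n6pufa_g",
    "fiber_sol_g",
    "fiber_insol_g",
    "alcohol_units",
    "cigarettes_per_day",
    "mvpa_met_h",
    "sleep_h",
]
DEA_OUTPUT_CANDIDATES = [
    "bacillus_permil",
    "bifidobacterium_permil",
    "lactobacillus_permil",
    "lactococcus_permil",
    "streptococcus_permil",
    "faith_pd",
]
DEA_COLUMNS = DEA_INPUT_CANDIDATES + DEA_OUTPUT_CANDIDATES

_Z75 = stats.norm.ppf(0.75)


@dataclass(frozen=True)
class MarginalSpec:
    """Continuous marginal with target mean/sd under truncation.

    kind:
        ``truncnorm``     -- truncated normal on [lower, upper];
        ``zi_truncnorm``  -- zero point-mass with probability 1-prevalence,
                             positive part truncated normal on (0, upper];
        ``lognorm``       -- log-normal matched to median and (q1, q3).
    The target mean/sd (or median/IQR) refer to the *marginal as observed*,
    zeros included for the zero-inflated kind.
    """

    kind: str
    mean: float = float("nan")
    sd: float = float("nan")
    lower: float = 0.0
    upper: float = float("inf")
    prevalence: float = 1.0  # P(nonzero), zi_truncnorm only
    median: float = float("nan")  # lognorm only
    q1: float = float("nan")
    q3: float = float("nan")

    def validate(self, name: str) -> None:
        if self.kind not in ("truncnorm", "zi_truncnorm", "lognorm"):
            raise ValueError(f"{name}: unknown marginal kind {self.kind!r}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{name}: prevalence must be in [0, 1]")
        if self.kind == "lognorm":
            if not (self.q1 < self.median < self.q3):
                raise ValueError(f"{name}: need q1 < median < q3")
        else:
            if not self.sd > 0:
                raise ValueError(f"{name}: sd must be > 0")
            if not self.lower < self.upper:
                raise ValueError(f"{name}: truncation lower must be < upper")


@dataclass(frozen=True)
class GenusSpec:
    """Zero-inflated log-normal relative abundance in per mille.

    ``prevalence`` is the probability of a nonzero abundance; ``median``,
    ``q1`` and ``q3`` describe the nonzero part only, as cohort tables
    customarily report them.
    """

    prevalence: float
    median: float
    q1: float
    q3: float
    cap: float = 1000.0  # relative abundance cannot exceed 1000 per mille

    def validate(self, name: str) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{name}: prevalence must be in [0, 1]")
        if not (0 < self.q1 < self.median < self.q3):
            raise ValueError(f"{name}: need 0 < q1 < median < q3")


@dataclass
class CohortConfig:
    n: int = 577
    seed: int = 20240927
    female_fraction: float = 366 / 577
    antibiotic_fraction: float = 3 / 577
    probiotic_fraction: float = 15 / 577
    marginals: dict[str, MarginalSpec] = field(default_factory=dict)
    genera: dict[str, GenusSpec] = field(default_factory=dict)
    # (column_a, column_b, target Pearson r on the observed scale)
    correlations: list[tuple[str, str, float]] = field(default_factory=list)
    missingness: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for frac_name in ("female_fraction", "antibiotic_fraction", "probiotic_fraction"):
            if not 0.0 <= getattr(self, frac_name) <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1]")
        for name, spec in self.marginals.items():
            spec.validate(name)
        for name, spec in self.genera.items():
            spec.validate(name)
        cols = set(self.marginals) | set(self.genera)
        for a, b, r in self.correlations:
            if a not in cols or b not in cols:
                raise ValueError(f"correlation target ({a}, {b}) names unknown columns")
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation target ({a}, {b}) = {r} out of (-1, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marginals"] = {k: asdict(v) for k, v in self.marginals.items()}
        d["genera"] = {k: asdict(v) for k, v in self.genera.items()}
        d["correlations"] = [list(t) for t in self.correlations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["marginals"] = {k: MarginalSpec(**v) for k, v in d.get("marginals", {}).items()}
        d["genera"] = {k: GenusSpec(**v) for k, v in d.get("genera", {}).items()}
        d["correlations"] = [tuple(t) for t in d.get("correlations", [])]
        return cls(**d)


def save_config(config: CohortConfig, path) -> None:
    """Write a cohort configuration as YAML."""
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> CohortConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return CohortConfig.from_dict(yaml.safe_load(fh))


def default_config() -> CohortConfig:
    """Study-population defaults.

    Lifestyle and covariate marginals carry the cohort's published mean
    (SD); genus abundances the published nonzero prevalence and nonzero
    median (IQR) in per mille; food-frequency items the published median
    (IQR) in times/day.  Correlation targets between DEA inputs and
    outputs carry the published input-output correlation grid; the
    inter-nutrient block (not published) uses values typical of
    FFQ-derived intakes so that energy adjustment has something to do.
    """
    inf = float("inf")
    m = {
        "age": MarginalSpec("truncnorm", 58.6, 14.6, lower=21.0, upper=84.0),
        "energy_kcal": MarginalSpec("truncnorm", 1545.0, 437.0),
        "fat_g": MarginalSpec("truncnorm", 47.8, 12.0),
        "sfa_g": MarginalSpec("truncnorm", 12.1, 3.1),
        "mufa_g": MarginalSpec("truncnorm", 17.2, 4.4),
        "n3pufa_g": MarginalSpec("truncnorm", 2.2, 0.6),
        "n6pufa_g": MarginalSpec("truncnorm", 10.9, 3.0),
        "fiber_sol_g": MarginalSpec("truncnorm", 2.1, 0.7),
        "fiber_insol_g": MarginalSpec("truncnorm", 8.2, 2.3),
        "salt_g": MarginalSpec("truncnorm", 4.4, 1.3),
        # roughly a quarter of participants drink; a third smoke
        "alcohol_units": MarginalSpec("zi_truncnorm", 0.3, 0.7, prevalence=0.25),
        "cigarettes_per_day": MarginalSpec("zi_truncnorm", 5.3, 10.1, prevalence=0.326),
        "mvpa_met_h": MarginalSpec("truncnorm", 12.0, 10.6),
        "sleep_h": MarginalSpec("truncnorm", 6.5, 1.0, lower=2.0, upper=14.0),
        "faith_pd": MarginalSpec("truncnorm", 30.8, 7.9),
        "bmi": MarginalSpec("truncnorm", 22.6, 3.1, lower=12.0),
        "egfr": MarginalSpec("truncnorm", 75.4, 16.0, lower=5.0),
        "hemoglobin": MarginalSpec("truncnorm", 13.9, 1.4, lower=5.0),
        "hba1c": MarginalSpec("truncnorm", 5.60, 0.53, lower=3.5),
        "ffq_yogurt": MarginalSpec("lognorm", median=0.2, q1=0.1, q3=1.0),
        "ffq_natto": MarginalSpec("lognorm", median=0.2, q1=0.1, q3=0.5),
        "ffq_seaweed": MarginalSpec("lognorm", median=0.2, q1=0.1, q3=0.5),
        "ffq_fried": MarginalSpec("lognorm", median=0.2, q1=0.1, q3=0.22),
        "ffq_coffee": MarginalSpec("lognorm", median=1.0, q1=0.5, q3=2.0),
    }
    g = {
        "bacillus_permil": GenusSpec(208 / 577, 1.81, 0.78, 3.09),
        # nonzero part not published for Bifidobacterium; same scale as peers
        "bifidobacterium_permil": GenusSpec(166 / 577, 2.5, 0.9, 7.0),
        "lactobacillus_permil": GenusSpec(236 / 577, 1.33, 0.37, 6.74),
        "lactococcus_permil": GenusSpec(86 / 577, 0.31, 0.16, 0.88),
        "streptococcus_permil": GenusSpec(569 / 577, 6.46, 2.28, 20.33),
    }
    corr = [
        # input x output grid (published)
        ("alcohol_units", "bacillus_permil", 0.08),
        ("alcohol_units", "lactobacillus_permil", 0.09),
        ("alcohol_units", "streptococcus_permil", 0.22),
        ("n3pufa_g", "bifidobacterium_permil", -0.11),
        ("n3pufa_g", "faith_pd", 0.09),
        ("fiber_sol_g", "bacillus_permil", 0.15),
        ("fiber_sol_g", "lactococcus_permil", 0.09),
        ("fiber_sol_g", "streptococcus_permil", 0.13),
        ("fiber_sol_g", "faith_pd", 0.18),
        ("fiber_insol_g", "lactobacillus_permil", -0.09),
        ("sleep_h", "bacillus_permil", 0.08),
        ("sleep_h", "lactobacillus_permil", 0.09),
        ("sleep_h", "streptococcus_permil", 0.22),
        # inter-nutrient block (typical FFQ structure, not published);
        # mutually consistent so the latent matrix stays positive definite
        ("energy_kcal", "fat_g", 0.50),
        ("energy_kcal", "sfa_g", 0.45),
        ("energy_kcal", "mufa_g", 0.50),
        ("energy_kcal", "n3pufa_g", 0.40),
        ("energy_kcal", "n6pufa_g", 0.40),
        ("energy_kcal", "fiber_sol_g", 0.30),
        ("energy_kcal", "fiber_insol_g", 0.30),
        ("energy_kcal", "salt_g", 0.40),
        ("fat_g", "sfa_g", 0.80),
        ("fat_g", "mufa_g", 0.85),
        ("fat_g", "n6pufa_g", 0.70),
        ("fat_g", "n3pufa_g", 0.40),
        ("fat_g", "salt_g", 0.30),
        ("sfa_g", "mufa_g", 0.75),
        ("sfa_g", "n6pufa_g", 0.50),
        ("sfa_g", "n3pufa_g", 0.30),
        ("mufa_g", "n6pufa_g", 0.70),
        ("mufa_g", "n3pufa_g", 0.40),
        ("n3pufa_g", "n6pufa_g", 0.40),
        ("fiber_sol_g", "fiber_insol_g", 0.60),
    ]
    miss = {"bmi": 8, "egfr": 40, "hba1c": 27, "hemoglobin": 29}
    return CohortConfig(marginals=m, genera=g, correlations=corr, missingness=miss)


# ---------------------------------------------------------------------------
# marginal fitting


def _truncnorm_params(mean: float, sd: float, lower: float, upper: float):
    """Solve for (loc, scale) so the truncated normal has the target moments."""
    lo, hi = lower, upper

    def moments(p):
        loc, log_scale = p
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale if np.isfinite(hi) else np.inf
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return np.array([float(m) - mean, np.sqrt(float(v)) - sd])

    sol = optimize.least_squares(moments, x0=[mean, np.log(sd)], xtol=1e-14, ftol=1e-14)
    resid = moments(sol.x)
    if not (abs(resid[0]) < 1e-6 * max(1.0, abs(mean)) and abs(resid[1]) < 1e-6 * sd):
        raise ValueError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} "
            f"on [{lower}, {upper}] (residual {resid})"
        )
    loc, scale = sol.x[0], float(np.exp(sol.x[1]))
    a = (lo - loc) / scale
    b = (hi - loc) / scale if np.isfinite(hi) else np.inf
    return a, b, loc, scale


def _marginal_ppf(spec: MarginalSpec | GenusSpec):
    """Return a vectorized quantile function F^{-1}(u) for one marginal."""
    if isinstance(spec, GenusSpec):
        sigma = (np.log(spec.q3) - np.log(spec.q1)) / (2 * _Z75)
        scale = spec.median  # exp(mu)
        p0 = 1.0 - spec.prevalence
        cap = spec.cap

        def ppf(u):
            u = np.asarray(u, dtype=float)
            out = np.zeros_like(u)
            nz = u > p0
            if spec.prevalence > 0:
                v = (u[nz] - p0) / spec.prevalence
                out[nz] = np.minimum(stats.lognorm.ppf(v, s=sigma, scale=scale), cap)
            return out

        return ppf

    if spec.kind == "lognorm":
        sigma = (np.log(spec.q3) - np.log(spec.q1)) / (2 * _Z75)
        scale = spec.median
        return lambda u: stats.lognorm.ppf(np.asarray(u, dtype=float), s=sigma, scale=scale)

    if spec.kind == "truncnorm":
        a, b, loc, sc = _truncnorm_params(spec.mean, spec.sd, spec.lower, spec.upper)
        return lambda u: stats.truncnorm.ppf(np.asarray(u, dtype=float), a, b, loc=loc, scale=sc)

    # zi_truncnorm: point mass at 0 with prob 1-p, positive part truncated
    # normal on (0, upper], moment-matched so the overall mean/sd hit target.
    p = spec.prevalence
    if p <= 0:
        return lambda u: np.zeros_like(np.asarray(u, dtype=float))
    mean_pos = spec.mean / p
    var_pos = (spec.sd**2 - p * (1 - p) * mean_pos**2) / p
    if var_pos <= 0:
        raise ValueError(
            f"zero-inflated spec mean={spec.mean}, sd={spec.sd}, prevalence={p} "
            "implies non-positive variance for the nonzero part"
        )
    a, b, loc, sc = _truncnorm_params(mean_pos, np.sqrt(var_pos), 0.0, spec.upper)
    p0 = 1.0 - p

    def ppf(u):
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        nz = u > p0
        out[nz] = stats.truncnorm.ppf((u[nz] - p0) / p, a, b, loc=loc, scale=sc)
        return out

    return ppf


# ---------------------------------------------------------------------------
# copula calibration

_GH_NODES, _GH_WEIGHTS = hermegauss(96)  # probabilists' Hermite
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2 * np.pi)
_U_MAX = np.nextafter(1.0, 0.0)  # keep quantile evaluations finite


def _norm_cdf(z):
    return np.clip(stats.norm.cdf(z), 1e-300, _U_MAX)


_GH_U = _norm_cdf(_GH_NODES)


def _transform_stats(ppf):
    vals = ppf(_GH_U)
    mean = float(_GH_WEIGHTS @ vals)
    var = float(_GH_WEIGHTS @ (vals - mean) ** 2)
    return vals, mean, var


def _realized_corr(ppf_a, stats_a, ppf_b, rho: float) -> float:
    """Pearson r of (F_a^{-1} Phi(Z1), F_b^{-1} Phi(Z2)) with corr(Z1,Z2)=rho."""
    vals_a, mean_a, var_a = stats_a
    z1 = _GH_NODES[:, None]
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * _GH_NODES[None, :]
    vals_b = ppf_b(_norm_cdf(z2))
    mean_b = float((_GH_WEIGHTS[:, None] * _GH_WEIGHTS[None, :] * vals_b).sum())
    var_b = float((_GH_WEIGHTS[:, None] * _GH_WEIGHTS[None, :] * (vals_b - mean_b) ** 2).sum())
    cov = float(
        ((_GH_WEIGHTS * (vals_a - mean_a))[:, None] * _GH_WEIGHTS[None, :] * (vals_b - mean_b)).sum()
    )
    return cov / np.sqrt(var_a * var_b)


def _latent_rho(ppf_a, stats_a, ppf_b, target: float) -> float:
    """Invert the copula correlation map so realized Pearson r == target."""
    if target == 0.0:
        return 0.0
    f = lambda rho: _realized_corr(ppf_a, stats_a, ppf_b, rho) - target
    hi = 0.995 if target > 0 else -0.995
    if f(hi) * f(0.0) > 0:  # f(0) = -target
        raise ValueError(f"target correlation {target} not attainable under this copula")
    return optimize.brentq(f, min(0.0, hi), max(0.0, hi), xtol=1e-5)


def _nearest_psd(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest correlation-like PSD matrix."""
    sym = (mat + mat.T) / 2
    for _ in range(100):
        w, v = np.linalg.eigh(sym)
        if w.min() >= eps:
            break
        w = np.clip(w, eps, None)
        sym = (v * w) @ v.T
        d = np.sqrt(np.diag(sym))
        sym = sym / np.outer(d, d)
        sym = (sym + sym.T) / 2
    w = np.linalg.eigvalsh(sym)
    if w.min() < -eps:
        raise ValueError("correlation matrix not positive semi-definite after repair")
    return sym


_CALIBRATION_CACHE: dict = {}


def _calibrate(config: CohortConfig):
    """Per-column ppfs and the repaired latent correlation matrix (cached)."""
    cols = list(config.marginals) + list(config.genera)
    key = (
        tuple(sorted((k, tuple(asdict(v).items())) for k, v in config.marginals.items())),
        tuple(sorted((k, tuple(asdict(v).items())) for k, v in config.genera.items())),
        tuple(sorted(config.correlations)),
    )
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    ppfs = {c: _marginal_ppf(config.marginals.get(c) or config.genera[c]) for c in cols}
    tstats = {c: _transform_stats(ppfs[c]) for c in cols}
    idx = {c: i for i, c in enumerate(cols)}
    latent = np.eye(len(cols))
    for a, b, r in config.correlations:
        rho = _latent_rho(ppfs[a], tstats[a], ppfs[b], r)
        latent[idx[a], idx[b]] = latent[idx[b], idx[a]] = rho
    latent = _nearest_psd(latent)
    chol = np.linalg.cholesky(latent + 1e-10 * np.eye(len(cols)))
    result = (cols, ppfs, chol)
    _CALIBRATION_CACHE[key] = result
    return result


# ---------------------------------------------------------------------------
# generation


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table, deterministic given ``config.seed``.

    Continuous variables come from a Gaussian copula with calibrated latent
    correlations; binary variables (sex, antibiotic/probiotic use) are
    independent Bernoulli draws.
    """
    config.validate()
    cols, ppfs, chol = _calibrate(config)
    rng = np.random.default_rng(config.seed)
    n = config.n
    z = rng.standard_normal((n, len(cols))) @ chol.T
    u = stats.norm.cdf(z)
    data = {"participant_id": np.arange(1, n + 1)}
    for j, c in enumerate(cols):
        data[c] = ppfs[c](u[:, j])
    data["sex_female"] = (rng.random(n) < config.female_fraction).astype(int)
    data["antibiotics"] = (rng.random(n) < config.antibiotic_fraction).astype(int)
    data["probiotics"] = (rng.random(n) < config.probiotic_fraction).astype(int)
    table = pd.DataFrame(data)
    # column order: id, demographics, lifestyle, covariates, FFQ, flags, outputs
    ordered = ["participant_id", "sex_female"] + [c for c in cols if c not in DEA_OUTPUT_CANDIDATES]
    ordered += ["antibiotics", "probiotics"] + [c for c in cols if c in DEA_OUTPUT_CANDIDATES]
    return table[ordered]


def inject_missingness(
    table: pd.DataFrame, counts: dict[str, int], seed: int
) -> pd.DataFrame:
    """Set exactly ``counts[var]`` cells of each variable to NaN, MCAR.

    DEA input/output columns are protected: the efficiency model requires
    complete data, so requesting missingness there is an error.
    """
    n = len(table)
    for var, count in counts.items():
        if var in DEA_COLUMNS:
            raise ValueError(f"refusing to inject missingness into DEA column {var!r}")
        if var not in table.columns:
            raise KeyError(f"unknown column {var!r}")
        if not 0 <= count <= n:
            raise ValueError(f"missingness count {count} for {var!r} out of [0, {n}]")
    out = table.copy()
    rng = np.random.default_rng(seed)
    for var in sorted(counts):
        count = counts[var]
        if count:
            rows = rng.choice(n, size=count, replace=False)
            out.iloc[rows, out.columns.get_loc(var)] = np.nan
    return out
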