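# Methods

`gutdea` implements a holistic "gut-microbiota efficiency" analysis.  Each
participant of a cross-sectional cohort is treated as a decision-making
unit (DMU) that converts lifestyle inputs — nutrient intakes, alcohol,
smoking, physical activity, sleep — into beneficial-microbiota outputs —
relative abundances (‰) of probiotic-relevant genera (*Bacillus*,
*Bifidobacterium*, *Lactobacillus*, *Lactococcus*, *Streptococcus*) and
Faith's phylogenetic diversity (FPD).  This note records the models, the
defaults and the choices made where the design was genuinely open.

## The efficiency model

For DMU *o* with inputs x_o and outputs y_o, the output-oriented
Banker–Charnes–Cooper (variable returns to scale) envelopment program is

    max φ   s.t.  Σ_j λ_j x_ij ≤ x_io   (each input i)
                  Σ_j λ_j y_rj ≥ φ y_ro (each output r)
                  Σ_j λ_j = 1,  λ ≥ 0.

φ ≥ 1 is the Farrell output expansion: the factor by which *all* outputs
could be scaled up by a convex combination of observed units using no more
of any input.  The efficiency score is 1/φ ∈ (0, 1]; score 1 defines the
frontier and "peers" are frontier units with λ_j above 1e−6 in the
optimum.  Each LP is solved with HiGHS (`scipy.optimize.linprog`).

Design choices:

* **One-phase LP.** No second-phase slack maximization; slacks are not
  reported and per-output shortfalls come from the λ decomposition below.
  At degenerate vertices the optimal λ is not unique; the solver's vertex
  is reported as-is.
* **Properties relied on.** Output-oriented VRS φ is invariant to positive
  rescaling of any column and to *translation of input columns* — the
  latter is what makes the pivot inversion of detrimental inputs (below)
  legitimate.  Both invariances, VRS ≥ CRS dominance, and inertness of
  dominated units are enforced as tests.
* **Oracle.** An independent brute-force check enumerates λ on a dense
  simplex grid (n ≤ 6 DMUs), keeps input-feasible points and maximizes
  min_r Σλy_r / y_ro.  The grid under-estimates φ by at most a few grid
  steps; LP and oracle agree within 2 steps on random problems.

## Preprocessing

DEA needs strictly positive, "more is better" columns.

* **Unit conversions**: salt (g/d) = 2.54 × sodium (g/d); alcohol units =
  grams / 21.
* **Energy adjustment** (residual method): each nutrient intake is
  regressed on total energy by OLS and replaced by residual + predicted
  intake at mean energy.  The adjusted column is exactly uncorrelated with
  energy and keeps its mean; it isolates diet composition from quantity.
  Applied to nutrient inputs only (MUFA, n3/n6-PUFA, soluble/insoluble
  fiber), not to alcohol, smoking, sleep or activity.
* **Detrimental-input inversion**: alcohol and cigarettes are mapped to
  pivot − value with pivots 5.5 units/d and 90 cigarettes/d, so lower
  consumption becomes a larger input.  A value at or above the pivot is an
  error (raise the pivot), never a silent clamp: a clamp would create
  non-positive inputs and collapse rankings.
* **Sleep**: missing self-reported sleep is imputed at 6.5 h/d (cohort
  mean and median).
* **Positivity shift**: a column containing zeros is shifted up by
  δ = half its minimum positive value.  The shift is strictly monotone
  (rankings preserved), exactly invertible, and recorded per column in a
  `TransformRecord` (kinds: inversion / shift / identity).  Output-oriented
  VRS DEA is translation-invariant in inputs, and for outputs the shift is
  small relative to the data by construction.  The whole-column shift was
  chosen over "replace zeros by δ" because it inverts without row
  bookkeeping; zeros still map to δ.  If energy adjustment pushes a small
  intake slightly below zero, the pipeline folds an extra offset into the
  same record.

## Variable screening

Every candidate input × output pair gets a Pearson correlation with a
two-sided t-test p-value and a Fisher-z 95% CI.  An input is excluded when
no output pair reaches p ≤ α (α = 0.05); a beneficial output is excluded
when it has no significant pair, or when its significant input
correlations are predominantly negative (wrong direction for a benefit).
Both rules are configurable: `input_rule` ("any" significant pair suffices
vs "all" pairs required) and `sign_rule` ("majority" vs "any_negative"),
because the literature's phrasing of such rules is typically loose.  No
multiple-testing correction is applied, matching common practice for this
screening style.  The pipeline screens on the measurement scale (after
energy adjustment, before inversion), so signs read in the raw direction;
the full grid is written out for audit.

## Lack-of-output decomposition

For an inefficient unit the optimal λ identifies a composite benchmark:
per output r, composite_r = Σ_peers λ_j y_rj, and

    lack_r = composite_r − own_r  ≥ 0.

This is deliberately *not* (φ−1)·own_r: the two coincide only for binding
outputs; the composite-minus-own definition decomposes the whole shortfall
per output.  Back-transformed lack = inverse(own + lack) − inverse(own)
through the recorded transform, which for an additive shift equals the
lack itself, expressed in ‰ or diversity units.  Consistency checks:
composite ≥ φ·own (within 1e−7) and composite/own = φ for binding
outputs.

## Tobit regression

Efficiency scores live in (0, 1] with a mass at 1, so associations with
covariates are estimated by a two-sided censored (Tobit) model with bounds
0 and 1: latent y* = Xβ + ε, ε ~ N(0, σ²); interior observations
contribute the normal density, boundary observations the tail probability.
The MLE runs in (β, log σ) from an OLS start via BFGS (Nelder–Mead
polish on stall); standard errors come from the observed information
(numerical Hessian, statsmodels `numdiff`), with the delta method for σ;
p-values from the normal Wald approximation.  Coefficients are reported
×10³ since effects on a 0–1 score are small.  Collinearity is diagnosed
with VIF_k = 1/(1 − R²_k) from OLS of covariate k on the others.
In simulation (n = 2000, σ = 0.05, ~5% ceiling censoring) coefficients
are recovered within sampling error and 95% Wald intervals cover at
≈ 94%.

## Missing data

Covariates (BMI, eGFR, HbA1c, hemoglobin) may be missing; DEA columns may
not.  Imputation is by chained equations with predictive mean matching:

* **Predictor selection (quickpred rule)**: predictor j is used for target
  k when |corr| ≥ 0.1 (pairwise complete, on values or on the target's
  missingness indicator) and the proportion of usable cases is ≥ 0.25;
  age, sex, the efficiency score and the DEA outputs are always forced in.
* **PMM step**: regress the target on its predictors over observed rows,
  draw (β, σ²) from their posterior, and impute each missing cell with the
  observed value of one of the 5 nearest donors by predicted mean.  The
  donor count, visit sequence (predictor-matrix row order) and iteration
  count are configurable; 5 donors is the conventional default.  Every
  imputed value therefore lies in the observed support.
* **Defaults**: m = 20 imputations × 50 iterations, independent seeded
  streams (`numpy` SeedSequence spawning), byte-reproducible.
* **Pooling (Rubin's rules)**: Q̄ = mean estimate, W̄ = mean squared SE,
  B = between-imputation variance, T = W̄ + (1 + 1/m)B, df by
  Barnard–Rubin, p from the t reference.
* **Model selection**: backward elimination on per-dataset Tobit p-values
  (drop the largest p until all ≤ 0.05; ties broken by column order); a
  covariate enters the final model when selected in ≥ 50% of datasets;
  the final model is refit on every dataset and pooled.  Per-dataset
  p-values (not pooled p at each step) are used so the per-dataset
  selection counts are meaningful.  An empty final model is reported, not
  raised.

## Synthetic cohort generator

The real cohort cannot be shared, so the generator emulates its published
structure; it is first-class, tested code, not a fixture.

* **Marginals**: lifestyle/covariate variables are truncated normals whose
  (loc, scale) are solved numerically so the *realized* mean/SD equal the
  published ones (e.g. energy 1545/437 kcal, sleep 6.5/1.0 h, FPD
  30.8/7.9; age truncated to the published 21–84 range).  Alcohol and
  cigarettes are zero-inflated: a published mean/SD pair like 0.3/0.7
  units/d is unreachable by any zero-truncated normal (mean/SD < 1, below
  the exponential limit), so a point mass of non-consumers is combined
  with a moment-matched positive part.  The smoker fraction 0.326 is
  published; the drinker fraction 0.25 is this package's choice.
* **Genus abundances**: zero-inflated log-normals; the nonzero part is
  matched to the published nonzero median/IQR (log-location = ln median,
  log-scale from the IQR ratio), prevalence to the published nonzero
  fractions; abundances are capped at 1000‰.  *Bifidobacterium*'s nonzero
  part is not published and is set to 2.5 (0.9, 7.0) ‰, the scale of its
  peer genera.
* **Dependence**: a Gaussian copula.  For each configured pair the latent
  correlation is calibrated by inverting the realized-Pearson map
  (2-D Gauss–Hermite quadrature + Brent root), so targets are met on the
  *observed*, post-transform scale within ±0.03 at n = 10,000.  The
  published input × output correlation grid supplies those targets; the
  inter-nutrient block is not published and uses a mutually consistent set
  typical of FFQ-derived intakes (fat↔subtypes 0.5–0.85, energy↔nutrients
  0.3–0.5).  The matrix is passed through an eigenvalue-clipping
  nearest-PSD repair; with the default targets the repair is a no-op
  (pre-repair minimum eigenvalue ≈ 0.04).
* **Missingness**: injected completely at random with exact per-variable
  counts (BMI 8, eGFR 40, HbA1c 27, hemoglobin 29 at n = 577); the true
  mechanism is unknown, MCAR is the neutral choice.  DEA columns are
  protected.

What the generator does *not* emulate: compositional coupling between
genera (outputs are tied only through the copula), any real covariate →
score structure (so regression stages see mostly noise coefficients),
measurement error of the FFQ, and seasonal/diurnal microbiota
fluctuation.  Passing tests therefore demonstrate correctness of the
machinery and faithfulness of the marginals/dependence — not that the
published cohort-level results (mean score 0.86, 14.2% efficient, the
published regression table) would be reproduced, which requires the real
data.  On synthetic cohorts of n = 577 the pipeline typically yields a
mean score of ~0.67 and ~8% efficient units.

## Numerical choices and problem sizes

* LP feasibility slack 1e−9; peer λ tolerance 1e−6; efficiency declared
  at score ≥ 1 − 1e−7.
* Truncated-normal moment matching via least squares on (loc, log scale),
  residual tolerance 1e−6 relative.
* Copula calibration nodes: 96-point Gauss–Hermite; calibration is cached
  per configuration.
* Test-suite simulation sizes: fidelity checks at n = 10,000; oracle
  equivalence on 100 random 5-DMU problems at grid step 0.02; Tobit
  coverage over 150 replicates of n = 2000; pipeline checks at n = 130–200
  with m = 2–3 imputations.  The acceptance script runs the pipeline at
  the study size (n = 577, m = 20, maxit = 50).

## Known limitations

* The optimal λ (hence the peer set and lack decomposition) can be
  non-unique for degenerate frontier faces; results are reported from the
  solver's vertex.
* The positivity transform is this package's documented rule; published
  back-transformed recommendation values depend on the original study's
  (unavailable) transform and are not comparable.
* Tobit SEs are observed-information Wald SEs; no robust/heteroskedastic
  variant.
* The generator draws binary variables (sex, antibiotic/probiotic use)
  independently of the copula block.
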