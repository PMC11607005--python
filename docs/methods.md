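# Methods

## The estimation problem

Administrative death records give, for each decedent, a name, demographic
fields, a birth year, and an integer age at death.  Deaths are reliably
captured only within a high-coverage calendar window (1988–2005 inclusive)
and at ages 65 and over.  For a cohort born in year c this means its death
distribution is observed only on the age interval implied by the window —
both the early deaths (before 1988 or before 65) and the late ones (after
2005) are missing, and the observable slice differs by cohort.  Naive
summaries (mean age at death, OLS on death age) are therefore biased in
cohort-composition-dependent ways, which is exactly the failure mode the
truncated maximum-likelihood estimator addresses.

## Gompertz proportional-hazard model

Adult mortality is modelled as a Gompertz hazard scaled log-linearly by
covariates, with age measured from an origin of 65:

    h_i(x | θ) = a0 · exp(b0 · (x − 65)) · exp(β · Z_i)

* `a0` — baseline hazard at 65 (per year, > 0; fitted on the log scale).
* `b0` — log-slope of the hazard with age (per year; ~0.09–0.16 for human
  adult mortality).
* `β` — covariate log hazard ratios; here a single foreign-born indicator
  per (group, sex) stratum, matching a per-group nativity contrast design.

Survival from 65 is S(x) = exp(−(a0 e^{βZ}/b0)(e^{b0(x−65)} − 1)), with the
exponential limit exp(−a0 e^{βZ}(x−65)) used smoothly as b0 → 0 (the
`(e^{bt}−1)/b` primitive is evaluated by `expm1`, switching to its series
below |b0| = 1e−6 in the gradient).

### Truncated likelihood

Each observation contributes the log density conditioned on being
observable in its window [L_i, U_i]:

    ℓ_i = w_i [ log h(x_i) + log S(x_i) − log(S(L_i) − S(U_i)) ]

with post-stratification weights w_i consumed as given (never constructed
here).  The denominator is evaluated as
`−H(L) + log(1 − exp(−(H(U) − H(L))))` using the standard two-branch
log1mexp form, so nearly-degenerate windows lose no precision; an exactly
degenerate window (S(L) = S(U) to machine precision) raises an error naming
the record.  The likelihood and its analytic gradient are vectorized;
optimization is L-BFGS-B over (log a0, b0, β) with up to three seeded jitter
restarts on non-convergence.  The covariance is the inverse observed
information from a central-difference Hessian of the analytic gradient; a
singular Hessian leaves the fit usable but flags intervals unavailable.

### Windows and the continuity correction

Recorded integer death ages are treated as mid-year events, x = age + 0.5
(unbiased under within-year uniformity of deaths; the data do not say more).
Per-record observable bounds are derived from birth year alone:

    L_i = max(65, 1988 − c_i − 0.5),  U_i = 2005 − c_i + 0.5

The half-year shifts keep the recorded-age rounding consistent with the
window arithmetic, so every record produced by the generator's
administrative-rounding rule (below) satisfies L_i ≤ x_i ≤ U_i; violations
are treated as filtering bugs and rejected loudly.  Exact birth dates are
not modelled — the birth-year approximation is a deliberate simplification
and is flagged here.

### Functionals and intervals

* Hazard ratios: exp(β) with exponentiated Wald 95% intervals.
* e65 = 65 + ∫₀^∞ S(65+t) dt, evaluated by adaptive quadrature (absolute
  and relative tolerance 1e−10, reported agreement with dense trapezoid
  summation at step 0.001 is ≤ 1e−6).  An exponential-integral closed form
  e^A E1(A)/b0 (A = a0 e^{βZ}/b0) serves as an independent cross-check and
  as the fast path inside bootstrap loops and calibration.  b0 ≤ 0 makes
  the integral divergent (improper distribution) and raises.
* Δe65 = e65(foreign-born) − e65(US-born).  Intervals for e65 and Δe65 use
  a seeded parametric bootstrap (default 1000 draws from the asymptotic
  normal of (log a0, b0, β)) because the delta method degrades for this
  nonlinear functional; the Wald machinery remains available for the
  coefficients themselves.

### Robustness companion

`fe_linear_check` runs (weighted) OLS of death age on the covariates plus
birth-year fixed effects.  The fixed effects absorb cohort-specific
truncation, mitigating but not removing the bias, so the regression is a
sign/sanity companion to the MLE, not an alternative estimator.  Collinear
covariates are rejected by name.

## Name classification

* **Normalization**: lowercase, accents folded to ASCII, digits dropped,
  hyphen/apostrophe kept (they carry name signal), whitespace collapsed to
  a separator symbol joining given name and surname.
* **BPE**: merges the most frequent adjacent pair until the inventory
  reaches `max_vocab` (default 512 — name corpora saturate quickly) or no
  pair occurs twice; ties break lexicographically on the (left, right) pair
  so training is deterministic.  The separator and the start/stop/unknown
  specials never merge.  Unknown characters map to the unknown token, so
  tokenization is total; minus specials, detokenization reproduces the
  normalized string exactly over the training alphabet.
* **Network**: embedding (32) → single LSTM layer (64) → sigmoid readout
  from the final hidden state; binary cross-entropy, Adam (lr 0.01,
  batch 256, 10 epochs), global-norm gradient clipping at 5.  The LSTM is
  implemented directly in numpy with backpropagation through time
  (gradient-checked against finite differences in the test suite); any
  gated recurrent cell fulfils the model contract, and this one is the
  plain LSTM.  Training, the stratified 80/20 split, and batch order are
  all driven by one seed, so identical (seed, data) pairs give identical
  models bit-for-bit.
* **Decision rule**: predict MENA when p ≥ 0.5 by default; a threshold
  sweep utility reports the precision/recall trade-off since the operating
  point is application-specific.  Inverse-frequency class weighting is
  available (off by default) for imbalanced training sets.
* **Group assignment**: records classified MENA are carved out of their
  prior coded group (classifier-overrides-coding), with the prior-code
  shares of reassigned records reported; a flag restricts reassignment to
  classifier ∩ prior-code instead.  The pipeline scores all records and
  unions with birthplace labels.

Zero-denominator conventions: precision (or recall) with an empty
predicted-positive (or positive) set is reported as 0.0 with a
`*_defined = False` flag.  Note that exact precision monotonicity in the
threshold is not a theorem — removing a true positive while false positives
remain can lower precision — so tests assert exact recall monotonicity and
precision monotonicity within a 0.02 fluctuation allowance on separable
fitted scores.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not any real population:

* **Mixture**: six groups at the reference sample's approximate shares
  (white 0.727, Black 0.170, Hispanic 0.055, Asian/Pacific Islander 0.035,
  MENA 0.0065, other 0.0065) with per-group foreign-born fractions (MENA
  0.61; others 0.03–0.74).  Sex is balanced; birth years are uniform on
  1890–1940 by default with an optional discrete cohort distribution.
* **Mortality**: for each (group, sex), (a0, b0) and the foreign-born log
  hazard are **calibrated at run time** so the model-implied US-born e65,
  foreign-born e65, and hazard ratio equal the reference-condition table
  (e.g. MENA men: 82.26 / 85.39 / 0.64, giving a0 ≈ 0.0115, b0 ≈ 0.118).
  Calibration is a nested bisection: a0 is pinned by the baseline e65 for a
  candidate b0, and the foreign-born e65 selects b0.
* **Recording**: continuous death ages are floored to completed years;
  death_year = birth_year + floor(age) + Bernoulli(fractional part), which
  keeps |death_year − birth_year − death_age| ≤ 1 as in administrative data
  and stays consistent with the fitting windows above.
* **Names**: order-2 character Markov chains per group (seeded Dirichlet
  transition tensors with boosted signature clusters, e.g. "kh"/"gh"/"al"
  for the MENA-like process), plus a 5% single-character
  substitution/transposition rate emulating transliteration variants.
  Mothers' names come from the same group's chain; fathers share the
  child's surname with probability 0.95.
* **Administrative fields**: MENA records are race-coded white/API/other at
  0.85/0.13/0.02 (ancestry invisible in the coding); race-report years span
  1972–2000 so the pre-1981 exclusion has bite; foreign birthplaces draw
  from small per-group code lists, US births from state codes.

All randomness descends from a single config seed through spawned
generators, so cohorts are byte-identical across runs and platforms.

**What the synthetic data does not show.**  Names are statistically
separable but linguistically fake: classifier metrics on them demonstrate
that the BPE+LSTM machinery extracts sub-word signal when it exists, not
that any particular accuracy is attainable on real names.  Likewise the
mortality regimes are exactly Gompertz-proportional, so parameter recovery
demonstrates estimator correctness under the model, not robustness to real
deviations (cohort trends in b0, non-proportionality, weight construction).

## Problem sizes and experiment design

Recovery experiments simulate 20,000 individuals per nativity group
(≈ 14,000 observable deaths after truncation), which puts the hazard-ratio
Monte-Carlo SE near 0.018 on the log scale; CI-coverage uses 200 replicates
of 10,000 per group; the likelihood oracle uses 100 random instances of
n ≤ 10 against quadrature-normalized brute force; classifier experiments
use 5,000 names per class (separable) and 2,000 per class (no-signal).
These sizes keep the whole suite at a couple of minutes on one CPU while
leaving effect-size recovery comfortably inside 3-SE tolerances.

## Known limitations

* Birth-date precision: observability windows are derived from birth year
  only (±half-year ambiguity absorbed by the continuity correction).
* The pooled multi-group model with interactions exists only as separate
  per-(group, sex) fits; a joint fit with shared b0 is future work.
* CIs are Wald (coefficients) and parametric bootstrap (functionals);
  profile likelihood is not implemented.
* The classifier is binary MENA/non-MENA; no multi-class taxonomy, no
  pretrained weights, no sub-word regularization.
* Post-stratification weights are consumed, never derived.
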