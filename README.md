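# namemort

Tools for studying the **immigrant mortality advantage** among populations
that are invisible in standard U.S. race coding — in particular Middle
Eastern and North African (MENA) Americans, who are folded into the "white"
category in federal classifications.  The package implements a two-stage
analysis over social-security-style death records:

1. **Name-based ancestry classification.**  Full names are tokenized into
   variable-length character clusters with byte-pair encoding (BPE) and fed
   to a gated recurrent (LSTM) network that outputs the probability a name
   is of MENA origin.  Training labels come from birthplace: the model is
   trained on the foreign-born subset (positive iff born in a MENA country),
   augmented with parents' names and excluding records whose last
   racial-identity report predates 1981 (the earlier three-category SSA
   coding is uninformative).  This catches spelling variants and
   transliterations that exact name-list matching misses.

2. **Over-65 mortality estimation from doubly-truncated deaths.**  Deaths
   are only observed in a high-coverage calendar window (1988–2005) and at
   ages ≥ 65, so both tails of each birth cohort's death distribution are
   censored away.  Mortality is modelled with a Gompertz proportional
   hazard,

   h_i(x) = a₀ · e^{b₀ x} · e^{β Z_i},

   with x measured from age 65, and fitted by maximum likelihood on the
   death-age density *conditioned on observability* in each record's
   cohort-specific age window [L_i, U_i]:

   ℓ = Σᵢ wᵢ [ log h(xᵢ) + log S(xᵢ) − log(S(Lᵢ) − S(Uᵢ)) ].

   From the fit the package reports hazard ratios exp(β) with Wald CIs, life
   expectancy conditional on surviving to 65 (e65 = 65 + ∫₀^∞ S(65+t) dt),
   and the foreign-born minus US-born e65 gap with parametric-bootstrap CIs.
   A linear regression of death age with birth-year fixed effects is
   provided as a robustness companion.

Because the real record database is an external multi-gigabyte download, the
package ships a first-class **synthetic cohort generator** that emulates its
statistical structure: six ethno-racial groups × two nativities, group-specific
name processes (order-2 character Markov chains with signature clusters like
"kh"/"gh"), Gompertz mortality calibrated to published reference e65 values
and hazard ratios, birth cohorts 1890–1940, and the 1988–2005 / age-65
observation window.  Every pipeline stage is testable offline.

## Worked example

Calibrate a mortality regime so that US-born e65 is 82.26 years and the
foreign-born hazard ratio 0.64 implies a foreign-born e65 of 85.39; simulate
the truncated design; refit; recover the effect:

```python
from namemort import (
    calibrate_from_e65, simulate_nativity_observations,
    GompertzProportionalHazards, nativity_effect,
)

params = calibrate_from_e65(e65_base=82.26, e65_alt=85.39, hazard_ratio=0.64)
print(f"calibrated a0={params.a0:.5f}, b0={params.b0:.4f}, beta_fb={params.beta[0]:.4f}")

x, Z, L, U, w = simulate_nativity_observations(params, n_per_group=20_000, seed=1)
fit = GompertzProportionalHazards().fit(Z, x, lower=L, upper=U, sample_weight=w)
eff = nativity_effect(fit, 0, n_boot=1000, seed=2)
print(f"hazard ratio  {eff['hazard_ratio']:.3f} [{eff['hr_lower']:.3f}, {eff['hr_upper']:.3f}]")
print(f"e65 US-born   {eff['e65_us']:.2f}  foreign-born {eff['e65_fb']:.2f}")
print(f"delta e65     {eff['delta_e65']:.2f} [{eff['delta_e65_lower']:.2f}, {eff['delta_e65_upper']:.2f}]")
```

prints

```
calibrated a0=0.01150, b0=0.1179, beta_fb=-0.4463
hazard ratio  0.633 [0.599, 0.669]
e65 US-born   82.19  foreign-born 85.42
delta e65     3.23 [2.87, 3.62]
```

i.e. from 14,101 observable deaths the truncated MLE recovers the generating
hazard ratio (0.64) and the 3.13-year foreign-born e65 advantage within
Monte-Carlo error.  The classifier side works the same way:

```python
from namemort import generate_names, train_name_classifier

pos = [f"{g} {s}" for g, s in generate_names("mena", 1500, rng_seed=1)]
neg = [f"{g} {s}" for g, s in generate_names("white", 1500, rng_seed=2)]
clf, metrics = train_name_classifier(pos + neg, [1]*1500 + [0]*1500, seed=0)
print(metrics.precision, metrics.recall, metrics.f1)   # ~0.93 / 0.95 / 0.94
```

## Command line

The full pipeline (generate/load → train classifier → reassign groups →
truncate → descriptive table → per-group/sex fits → robustness table) runs as

```bash
namemort run-all -n 20000 --seed 1 --out-dir out/
namemort simulate -n 10000 --seed 1 --out records.csv
namemort train-names --records records.csv --out-model model.npz
namemort classify --records records.csv --model model.npz --out scored.csv
namemort fit --records scored.csv --out-dir out/
```

Outputs are `table1.csv` (descriptives), `table2.csv` (hazard ratios and
e65 effects), `table3.csv` (e65 by nativity), `appendix_fe.csv`
(fixed-effects linear check), classifier metrics, the serialized model and
BPE vocabulary, and a run manifest; every file carries the config hash and
seed.

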