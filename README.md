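# cogslope

Do polygenic scores predict not just the *level* of cognitive ability in
older age, but the *rate of its decline*?  Answering that requires an
unusual combination of machinery: polygenic scoring from GWAS summary
statistics, a hierarchical **"factors of curves"** structural equation
model that extracts a general cognitive level factor and a general
cognitive slope factor from a multi-test, multi-wave battery, and
full-information maximum likelihood (FIML) so that the substantial,
ability-dependent attrition of longitudinal ageing cohorts does not bias
the growth estimates.

`cogslope` implements that whole pipeline as a tested Python library with
a CLI, together with a synthetic-cohort generator that reproduces the
design of the study it emulates: 13 cognitive tests in four correlated
domains measured at four waves (0, 2.98, 6.71, 9.78 years apart),
monotone score-dependent dropout from 1091 to 550 participants, a
childhood (age-11) cognitive score, fourteen trait polygenic scores with
small standardized effects on the level (|β| ≈ 0.02–0.30), and a binary
APOE-e4-like indicator with a slope effect (β = −0.30).  Because the
generator's population moments are available in closed form, every stage
— clumping, FIML, factor scores, mediation, FDR — is validated against
independent oracles and parameter-recovery experiments without any data
download.

It is aimed at quantitative researchers in cognitive epidemiology and
statistical genetics who want a transparent, self-contained reference
implementation of the level-and-slope analysis.

## The model

For test *t* at wave *w* with time basis λ_w:

    y_itw = I_it + λ_w · S_it + ε_itw              (latent growth curve)
    I_it  = a_t · L_d(t),i + e_it                  (level hierarchy)
    S_it  = b_t · Sl_d(t),i + f_it                 (slope hierarchy)
    L_di  = λ_d · gL_i + u_di,   Sl_di = μ_d · gS_i + v_di

with gL (general level) and gS (general slope) scaled to unit variance.
Genetic predictors x enter as exogenous regressions gL ← γ_L x,
gS ← γ_S x; estimation maximizes the conditional FIML likelihood over
missingness patterns with an analytic gradient, and effects are reported
standardized with respect to the outcome (and the predictor when
continuous).  Polygenic scores are built by allele harmonization, greedy
LD clumping (r² > 0.25 within ±250 kb, ascending p), p-value thresholding
(p ≤ 1.0 by default), and dosage-weighted summation.

## Worked example

```python
import pandas as pd
from cogslope import GenerativeSpec, simulate_cohort
from cogslope.sem.foc import (FoCModelSpec, fit_foc, residualize_scores,
                              variance_decomposition)
from cogslope.sem.indices import fit_indices
from cogslope.association import single_predictor_association

spec = GenerativeSpec(seed=11)               # study-sized cohort, n=1091
cohort = simulate_cohort(spec)

resid = residualize_scores(cohort, spec.test_battery)  # age + sex removed
frame = pd.concat([resid, cohort.drop(columns=resid.columns)], axis=1)

fspec = FoCModelSpec.from_generative(spec)
baseline = fit_foc(frame, fspec, seed=0)
ind = fit_indices(baseline.fit)
dec = variance_decomposition(baseline).groupby("outcome").general_share.mean()
print(f"RMSEA={ind.rmsea:.3f} CFI={ind.cfi:.3f} SRMR={ind.srmr:.3f}")
print(f"general share of level variance: {100*dec['level']:.1f}%")
print(f"general share of slope variance: {100*dec['slope']:.1f}%")

for r in single_predictor_association(frame, fspec, "apoe_e4", baseline=baseline):
    print(f"APOE e4 -> {r.outcome}: beta={r.beta:.3f} (SE {r.se:.3f}), p={r.p:.2g}")
```

Output from this exact script:

```
RMSEA=0.007 CFI=0.999 SRMR=0.025
general share of level variance: 43.1%
general share of slope variance: 66.4%
APOE e4 -> level: beta=-0.120 (SE 0.072), p=0.096
APOE e4 -> slope: beta=-0.170 (SE 0.089), p=0.056
```

The general factor carries roughly 41% of level variance and 70% of
slope variance in the generating population; the fitted shares above are
one cohort's estimates.  The APOE indicator was generated with a slope
effect of −0.30, and this replicate's estimate (−0.17 ± 0.089) has a
95% CI covering it — the recovery experiments below do this
systematically over 20 replicates.

The same study runs end to end from the shell:

```bash
cogslope run-all --n 300 --seed 9 --out-dir run1
```

writing Table-shaped CSVs (own-phenotype validation, per-test growth,
level/slope associations with FDR, lifetime change), the fitted-model
JSON, the mediation decomposition and a run log, byte-identically for a
given config and seed.

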