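# patsep

Behavioural pattern-separation scoring and lifespan structure–function
modelling for hippocampal subfield studies.

`patsep` is a Python toolkit for analysing how mnemonic-discrimination
performance relates to hippocampal subfield volume and activation across
the adult lifespan. It is aimed at cognitive-neuroscience and
biostatistics researchers who work with mnemonic similarity task data and
subfield-level imaging summaries (CA1, CA3 and dentate gyrus per
hemisphere), and who need age-varying — not merely age-adjusted — models
of brain–behaviour association.

## What it does

**Task scoring.** Retrieval sessions of a mnemonic similarity task
(targets / similar lures / novel foils, answered "old"/"similar"/"new")
are reduced to two bias-corrected scores, with missing responses excluded
from numerator and denominator alike:

- LDI (lure discrimination index) = p("similar"|lure) − p("similar"|foil)
- CRS (corrected recognition score) = p("old"|target) − p("old"|foil)

**Penalized-spline GAMs.** A Gaussian additive-model engine
(statsmodels-style `GAM` / `GAMResults`) with cubic P-spline smooths
s(x), tensor-product interactions te(x, age) / ti(x, age), and
varying-coefficient terms s(age, by=x); smoothing parameters chosen by
REML (or GCV), per-term effective degrees of freedom, Wald F tests,
conditional AIC, and smooth-versus-linear selection via AIC plus an
exactly calibrated nested analysis-of-deviance F test.

**Floodlight (region-of-significance) analysis.** For any fitted
interaction model, the predicted-outcome difference between the
moderator's third and first quartile, d(age), is traced over the age
range with pointwise 95% confidence bands; the age intervals where the
band excludes zero are the regions in which the moderator is associated
with the outcome.

**Synthetic lifespan cohorts.** A calibrated generator produces
participant tables (three recruitment strata over ages 21–73, six
subfield volumes with linear age slopes, six activation contrasts with
age-varying volume coupling, a nonlinearly declining latent LDI with
midlife DG-volume and CA3-activation moderation, a linearly declining
CRS) plus trial-level sessions whose computed scores are unbiased for the
latent ones. Every analysis stage is therefore testable end-to-end
without any subject data.

**Pipeline & CLI.** `run_full_analysis` fits the full model sequence
(main effects, tensor interaction, varying coefficient — per subfield ×
hemisphere × predictor kind, with sex and education covariates), selects
the most parsimonious model per combination, and attaches floodlight
regions to every selected interaction. The `patsep` command exposes
`simulate`, `score`, `analyze`, `floodlight` and `power`.

## Worked example

```python
import pandas as pd
from patsep import (
    default_config, simulate_cohort, GAM, compare_models,
    difference_curve, regions_of_significance,
)

cohort = simulate_cohort(default_config(), seed=7, n=500)

smooth = GAM(cohort, "ldi ~ s(age) + sex + education").fit()
print(smooth.summary())

m1 = GAM(cohort, "ldi ~ dg_left_vol + s(age) + sex + education").fit()
m2 = GAM(
    cohort,
    "ldi ~ s(dg_left_vol) + s(age) + ti(dg_left_vol, age) + sex + education",
).fit()
print(compare_models(m1, m2))

curve = difference_curve(m2, "dg_left_vol")
regions = regions_of_significance(curve)
for (lo, hi), sign in zip(regions.intervals, regions.signs):
    print(f"significant {lo:.1f}-{hi:.1f} y, sign {sign:+d}")
```

prints (seed 7):

```
Gaussian additive model: ldi ~ s(age) + sex + education
n = 500   edf(total) = 5.55   AIC = -522.95   deviance = 10.02   scale = 0.02027   (reml)

term                             edf         F           p
s(age)                          2.55     87.11    2.90e-45
sex                             1.00      1.24      0.2658
education                       1.00      0.06      0.8083

smoothing parameters: s(age): 35.8
dAIC=-41.07  F=3.550 (df=24)  p=0.0000  selected=smooth
significant 28.6-57.0 y, sign -1
significant 65.5-73.0 y, sign +1
```

The age smooth confirms the nonlinear LDI decline (edf > 1, F = 87.1);
the tensor-interaction model beats the main-effects model (ΔAIC < 0,
nested F significant); and the floodlight analysis finds a midlife window
in which higher left-DG volume goes with *lower* discrimination (negative
sign), reversing in late life — the age-varying moderation the generator
builds in over ages ~42–60.

From a shell, the same study-scale run is:

```sh
patsep simulate --n 53 --seed 7 --out sim/
patsep analyze sim/cohort.csv --out report/ --seed 7
patsep power --r2 0.221 --alpha 0.05 --power 0.80 --groups 3
```

The last command prints `N = 38` under both the ANOVA and the regression
convention of the noncentral-F power analysis.

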