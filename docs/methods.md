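# Methods

This note documents the statistical machinery in `patsep`: what each model
computes, the conventions behind the numbers it reports, what the synthetic
cohort generator does and does not emulate, and the design choices made
where the design was genuinely open.

## 1. Task scoring

A mnemonic similarity session consists of retrieval trials of three kinds
— exact repeats (targets, n = 50 by design), perceptually similar objects
(lures, n = 100) and novel objects (foils, n = 50) — each answered "old",
"similar" or "new". Two bias-corrected scores summarise a session:

```
LDI = p("similar" | lure)  - p("similar" | foil)     (lure discrimination)
CRS = p("old"     | target) - p("old"    | foil)     (target recognition)
```

All probabilities are conditioned on *valid* trials: a trial without a
behavioural response is removed from both the numerator and the
denominator of its condition. Both scores live in [-1, 1]; a zero-valid
denominator is an error, never silently zero. Location (quadrant) and
confidence second judgements are parsed and retained but never scored.
Scores are carried at full floating precision throughout.

## 2. Synthetic cohort generator

The generator (`patsep.cohort`) produces participant tables with the joint
structure the downstream models assume. It emulates the *end products* of
an imaging study — normalized subfield volumes (mm³/ICV × 1000, "au"),
BOLD activation contrasts, task scores — not images or time series.

**Age.** Stratified sampler: uniform within [21, 30], [40, 50], [60, 73]
with weights 18 : 18 : 17 (exact per-stratum counts at the design size via
largest-remainder apportionment; 18/18/17 at n = 53). A continuous-uniform
sampler over [21, 73] is a config switch. Analytic moments of the sampler
(mean ≈ 45.27 y, SD ≈ 16.9 y) are computed by per-stratum quadrature and
used for all calibrations below.

**Demographics.** Sex: Bernoulli, p(female) = 0.57. Education: an 8-level
ordinal scale, sampled from a discretized normal (mean 5.51, SD 1.6)
truncated to 2–8. Neither influences any other variable in the generator
— the covariate adjustment downstream is therefore a pure noise control,
and adjusted and unadjusted slopes estimate the same quantity.

**Volumes.** Each of the six subfield-hemisphere volumes is
`intercept + slope·(age − age_center) + noise`, with the intercept equal
to the target population mean (e.g. left CA1 30.63 au), `age_center` the
sampler mean, and slopes −0.06 (left CA1), −0.02 (left DG), −0.03
(right DG) au/year, 0 elsewhere. The residual SD is set analytically so
the *marginal* SD equals its target (e.g. 3.2 au for left CA1) under the
age distribution. Residuals are independent across subfields by default;
an equicorrelation parameter is exposed because the joint covariance
between subfields is an assumption, not an emulated fact.

**Activations.** Gaussian with the target means/SDs. Two subfields carry
an age-varying coupling to their own (standardized, age-adjusted) volume:
left CA1 (+8 au/SD in the 20s, −8 au/SD from the mid-50s) and left DG
(0 until the mid-40s, −18 au/SD from the early 50s). Residual SDs are
again reduced analytically so marginal SDs stay on target.

**LDI.** Latent score = g(age) + moderation + N(0, σ²), clipped to
[−1, 1] (clipping events are logged; at the default calibration ≈ 0.1% of
LDI draws clip). The age trend is a logistic decline

```
g(age) = offset + 0.30 − 0.28 / (1 + exp(−(age − 52)/5))
```

— flat through the 20s–30s, declining from the 40s, consistent with a
monotone mnemonic-discrimination decline that begins in the fourth decade.
The `offset` is calibrated by quadrature so the population mean is exactly
0.16. Moderation terms are `b(age) · z`, where `z` is the standardized
age-adjusted residual of the moderator and `b` a piecewise-linear
(bilinear-ramp) coefficient in LDI units per moderator-SD:

* left DG volume: 0 before 40, −0.08 over ≈ 46–56, back through 0 near 61,
  +0.05 after 66 (midlife cost, late-life benefit);
* right DG volume: 0 before 40, −0.07 over ≈ 45–52, 0 after 57;
* left CA3 activation: +0.06 before 40, 0 by 48, −0.05 after 64.

The amplitudes were fixed once so that a floodlight analysis on an n ≈ 500
cohort detects the midlife left-DG window with power > 0.8. σ is then set
by quadrature so the marginal LDI SD equals 0.18.

**CRS.** Linear: mean 0.58 at the mean age, slope −0.007/year, residual SD
chosen for a marginal SD of 0.25. Because the mean sits near the upper
truncation bound, ≈ 4–5% of draws clip at 1; the adjusted OLS slope
recovered from large cohorts is therefore mildly attenuated (≈ −0.0067
rather than −0.0070), an intended consequence of bounded scores.

**Trials.** Given latent (LDI, CRS), responses are multinomial with
p(similar|lure) = foil_similar_rate + LDI, p(similar|foil) =
foil_similar_rate (default 0.30), p(old|target) = foil_old_rate + CRS,
p(old|foil) = foil_old_rate (default 0.32); remaining mass splits evenly.
This is the simplest model that makes session scoring unbiased for the
latent values by construction (whenever no probability clips). Missing
responses are flagged, never deleted.

**What the generator does not emulate:** measurement error in
segmentation, non-Gaussian activation tails, volume–education or
volume–sex associations, practice/order effects, and any joint covariance
between subfields. Tests passing on synthetic cohorts therefore
demonstrate *statistical correctness of the machinery under the assumed
structure*, not robustness to real-data violations of it.

## 3. The GAM engine

Gaussian additive models are fitted by penalized least squares
(`patsep.gam`), statsmodels-style: `GAM(data, formula).fit()` returns a
`GAMResults` with coefficients, posterior covariance, per-term effective
degrees of freedom, AIC, deviance and `summary()`.

* **Bases.** Univariate smooths: k = 10 cubic B-splines on equally spaced
  knots over the observed range, second-order difference penalty
  (P-splines). Smooths are centered (sum-to-zero over the data) by an
  orthogonal reparameterization so the intercept stays identifiable.
* **Tensor products.** `te(x, z)`: row-wise Kronecker of two k = 5
  marginal bases, penalty S₁⊗I + I⊗S₂ under a **single smoothing
  parameter per term** (an isotropy assumption that keeps the REML
  determinant block-separable). `ti(x, z)` applies the sum-to-zero
  constraint to each margin first, yielding a pure-interaction surface
  for use alongside marginal smooths.
* **Varying coefficients.** `s(age, by=x)` multiplies the age basis by x;
  its penalty null space contains x and x·age, so no separate linear x
  term is entered beside it.
* **Smoothing selection.** REML by default: λ̂ minimizes
  (n−M_p)·log D(λ) + log|X'X+S(λ)| − Σ r_j log λ_j, with D the penalized
  deviance, M_p the count of unpenalized dimensions and r_j the penalty
  ranks; optimized by Nelder–Mead over log λ from three starts
  (deterministic). GCV is available as an option. On a common test
  function the fit agrees with an independent P-spline REML implementation
  to edf ± 0.01 and fitted-value RMSE ~ 1e-4 (see the oracle test).
* **Uncertainty.** Coefficient covariance is the Bayesian posterior
  (X'X+S)⁻¹·scale with scale = RSS/(n − edf_total); per-term edf are block
  traces of (X'X+S)⁻¹X'X.
* **AIC.** Conditional Gaussian AIC: −2·loglik(σ̂²_ML) + 2·(edf_total + 1).
  Stated explicitly because AIC definitions for penalized models differ.
* **Per-term F tests.** Wald statistics are computed on the term's fitted
  values with their posterior covariance, using a pseudo-inverse truncated
  to rank round(edf) in the directions of largest fitted-value variance
  (the least-shrunk, i.e. effectively estimated, directions), referred to
  F(rank, n − edf_total). This is the reported "F" for smooth terms; the
  reference-df convention is exactly this rank.

### Smooth-versus-linear comparison

`compare_models(restricted, full)` combines two signals:

1. ΔAIC of the two penalized (REML) fits;
2. an analysis-of-deviance F test computed on **unpenalized refits** of
   both models — a classical nested linear-model F test on the extra
   basis dimensions, F(Δdf, n − p_full), which is exactly calibrated
   under the Gaussian null.

The richer model is selected only if ΔAIC < 0 **and** p < α; otherwise
the more parsimonious model is kept (degenerate comparisons — no extra
df — always keep the restricted model). The penalized-edf version of the
deviance test was deliberately rejected: with data-driven smoothing
parameters its fractional-df F distribution is badly anti-conservative
(measured type-I selection ≈ 0.11 at n = 300 instead of 0.05), while the
convention used here measures ≈ 0.04 with uniform null p-values.

### Power / sample size

`power_sample_size(R², α, power, k)` converts R² to Cohen's f² =
R²/(1−R²), takes noncentrality f²·N, and returns the smallest N whose
noncentral-F power reaches the target. Both the k-group ANOVA convention
(u = k−1, v = N−k) and the u = k−1 predictor regression convention
(v = N−u−1) are reported; with these df they coincide. At R² = 0.221,
α = 0.05, power 0.80, k = 3 both give N = 38.

## 4. Floodlight (region of significance)

For a fitted interaction model, the moderator is set to its 25th and 75th
percentile *values* (the natural reading of a "first vs third quartile"
contrast; configurable), covariates are fixed at reference levels
(categorical: sample mode; numeric: sample mean — reference levels are a
convention, stated here because results depend on them only through the
intercept), and

```
d(age) = E[y | age, m = Q3] − E[y | age, m = Q1]
```

is evaluated on a 201-point age grid with pointwise SE √(c'Vc) from the
coefficient posterior. Regions of significance are maximal runs where the
(1−α) CI excludes zero, split at sign changes of d, with endpoints
linearly interpolated at the |t| = z crossing (grid endpoints optionally
reported instead). Pointwise intervals are the default, matching the
stated 95%-CI rule; a simultaneous max-|t| band (simulated from the
coefficient posterior) is available but off by default. One-sided testing
(z₁₋α instead of z₁₋α/₂) is an explicit flag, since a one-sided reading
of a late-life window is a post-hoc choice that should be visible in code.

## 5. Pipeline

`run_full_analysis` fits, per subfield-hemisphere × predictor kind
(volume, activation), with sex and education as linear covariates:

* Model 1: `y ~ predictor + s(age)` (main effects);
* Model 2: `y ~ s(predictor) + s(age) + ti(predictor, age)` (tensor
  interaction; the reported interaction F is the pure-interaction term);
* Model 3: `y ~ s(age) + s(age, by=predictor)` (linear-predictor ×
  smooth-age varying coefficient).

Model 2 and Model 3 are each compared against Model 1; the best-model
flag goes to the interaction only when it wins its comparison, with
lower-AIC (fewer edf on an effective tie, |ΔAIC| < 2) breaking a double
win. Every selected interaction gets a floodlight analysis. Further
stages: age main effects on LDI/CRS/volumes/activations (smooth-vs-linear
selected, slope or edf/F reported accordingly), volume × age → activation
per subfield, and volume × activation → LDI (linear product term beside
smooth age). Failures are quarantined per combination. p-values are
uncorrected — the model count is logged prominently and a
Benjamini–Hochberg column is optional — matching an exploratory
multi-model design. Education enters as a linear ordinal covariate.

Reports are fully regenerable from (config, seed): the provenance block
carries a content hash of the cohort table and the seed, and no wall-clock
timestamps enter the report, so identical inputs give byte-identical
output.

## 6. Problem sizes used in tests

Simulation-based checks run at sizes chosen to keep Monte-Carlo error
well below the tolerances they assert: scoring round trip 5,000 sessions;
null selection calibration 1,000 replicates at n = 300; floodlight
coverage 500 replicates at n = 300; midlife-window recovery 200 replicates
at n = 500; generator calibration n = 100,000 (means) and n = 50,000
(slopes). The acceptance script re-simulates at the same sizes.

## 7. Known limitations

* Gaussian outcomes only; no random effects or autocorrelation.
* One smoothing parameter per tensor term (isotropic penalty).
* The per-term F convention for penalized smooths is approximate;
  exactness holds only for the unpenalized nested comparison.
* Bounded scores are handled by clipping, not by a censored likelihood;
  heavy clipping (high means with large SDs) attenuates recovered slopes.
* The generator's independence assumptions (between subfields, and
  between imaging variables and demographics) are conventions, not data.
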