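# Methods

`probdose` implements a probabilistic dose–response (hazard characterization)
pipeline for animal toxicology summary data. This note records the model, its
assumptions, the defaults, and the numerical choices.

## The target quantity

The output of an assessment is the uncertainty distribution of the *target
human dose* `HD_M^I`: the dose at which a fraction `I*` of the human
population experiences effects of magnitude at least `M*`, where `M*` is
measured in a *toxicologically equivalent effect metric*. The effect metric
depends on the endpoint class:

| endpoint class | effect metric | benchmark response used |
|---|---|---|
| continuous (body weight, hematocrit, ...) | percent change vs. control | relative change of `M*` in the median response |
| deterministic quantal (graded lesions) | severity category | 50% incidence (ED50) of the reported category |
| stochastic quantal (tumors, malformations) | extra risk of the discrete outcome | extra risk of `M*` |

The distinction between the two quantal classes is interpretive: a
*deterministic* quantal response records whether an underlying continuous
severity crossed a cut point (so the observed incidence curve reflects
study variation, and its ED50 estimates the dose at which the median subject
reaches the cut point), while a *stochastic* quantal response is read as an
individual probability of a discrete outcome (so the curve's shape itself
carries information about individual risk). `data_io.quantize_continuous`
makes the first interpretation concrete: dichotomizing continuous
individual data at a cut point produces a quantal dataset whose ED50
estimates the continuous benchmark dose at the cut point — a property the
test suite verifies by simulation.

## Step 1 — animal benchmark dose (`models`, `bmd`)

Continuous endpoints are modeled as lognormal individual responses whose
median follows either the exponential family `a·exp(b·d^g)` or the Hill
family `a·(1 + (c−1)·d^g/(b^g + d^g))`. Group summaries (arithmetic mean,
SD) are converted to log-scale sufficient statistics and fitted by maximum
likelihood with a common log-SD across groups (profiled out analytically).
For the exponential family, `ln a` and `b` are profile-linear given the
power `g`, reducing the fit to a 1-D bounded search — exact and fast, which
matters inside the bootstrap.

Quantal endpoints are fitted under the binomial likelihood with six
families (logistic, log-logistic, log-probit, Weibull, gamma, second-degree
multistage with nonnegative coefficients). All but the plain logistic use
an independent background, `P(d) = c + (1−c)·F(d)`; the logistic carries
its background in the intercept, and extra risk is always computed by the
general form `(P(d) − P(0))/(1 − P(0))`, which for the independent-
background families reduces to `F(d)` — making the extra-risk BMD invariant
to the background parameter. Optimization uses L-BFGS-B from five
deterministic starting points on dose scaled by the maximum tested dose
(design-independent bounds); ties break by the highest likelihood. Bootstrap
refits start from the original estimate only, keeping refits in the same
likelihood basin.

Goodness of fit is a likelihood-ratio test against the saturated model,
chi-square with `df = groups − parameters` (p = 1 when saturated); models
with p > 0.05 are *accepted*. A type-I-error simulation in the test suite
checks the 5% screen is calibrated.

BMD uncertainty is a parametric bootstrap: per accepted family, datasets are
re-simulated from its fitted sampling model — binomial counts for quantal
data; for continuous data the sufficient statistics are resampled (group
log-mean ~ Normal(log fitted median, σ²/n); group log-variance ~
σ²·χ²₍ₙ₋₁₎/(n−1)) — the same family refitted, and the BMD recomputed.
Failed refits (including benchmark responses not reached within 10× the
maximum tested dose) are dropped and counted, never retried; >20% failures
raises a warning. Default 1000 bootstrap samples per model.

Accepted models are pooled with equal weight: every model contributes the
same number of samples (families short of the common count are resampled up
with replacement) and the clouds are concatenated — *pool first, then
resample* to the Monte Carlo size. The alternative order (resample each
model, then pool) is equivalent in distribution; the pooled order is fixed
here for reproducibility. A 90%-interval coverage simulation (500 replicate
Weibull studies) is the primary statistical check of this step.

## Step 2 — adjustments to the median human (`adjustments`)

`HD_median = AD_M* × DAF / (AHU × OU)`, elementwise per uncertainty draw:

* **DAF** (oral): `(BW_animal/BW_human)^(1−α)` with α ~ Normal(0.7, 0.024).
  Inhalation: user-supplied RDDR/RGDR times `exp(ε)`, ε ~ Normal(0, σ_DAF);
  no default σ_DAF is shipped — it must come from propagated dosimetry
  uncertainty or expert judgment.
* **AHU**: lognormal with geometric mean equal to the CSAF/DDEF point value
  (default 1) and default GSD 2.0 — residual chemical-specific
  interspecies toxicokinetic/toxicodynamic uncertainty beyond the DAF.
* **OU**: product of independent lognormal study-condition components
  (duration, route, pattern); empty by default (adequate chronic study).
  Components may be given as (point, GSD) or as a (p5, p95) multiplicative
  interval, converted via the 1.645 z-points.

Default human body weight is 70 kg. These defaults bracket both traditional
factors of 10 (interspecies and intraspecies) within their 95% intervals —
asserted by simulation in the tests.

## Step 3 — human variability (`engine`)

Equipotent doses across humans are lognormal with log-SD `σ_H`, itself
uncertain: lognormal with geometric mean 0.746 and geometric SD 1.59 (from
meta-analyses of human toxicokinetic and toxicodynamic variability). The
sensitive-to-median ratio at incidence `I*` is `HV_I* = exp(z_I*·σ_H)`
(< 1 for `I* < 0.5`), giving `HD_M^I = HD_median × HV_I*` per draw. The
hierarchical ordering is strict: all uncertainty quantities are drawn
jointly first (one index `j` pairs AD, DAF, AHU, OU, σ_H), and variability
enters only through `σ_H[j]` — the inner variability loop can never re-pair
uncertainty draws. Each stochastic stage consumes a named substream of the
single master seed.

The incidence-versus-dose relation per draw is
`I(d) = Φ((ln d − ln HD_median)/σ_H)`; evaluating it at `HD_M^I` returns
`I*` identically (checked to 1e-12 per draw). The probabilistic RfD is the
`(1 − confidence)` quantile (default 5th percentile) of the `HD_M^I` cloud.

For stochastic quantal endpoints, the expected *population* incidence at a
human dose is the average of the individual extra risk over the lognormal
population: per uncertainty draw `j` (a bootstrap parameter vector θ[j]
paired with adjustment draws), `n_inner` standard-normal scores z are drawn
and `f(exp(z·σ_H[j])·HD·AHU[j]·OU[j]/DAF[j], θ[j])` is averaged. The same
inner z sample is reused across draws (common random numbers — reduces
between-draw noise without biasing the inner average); `n_inner < 100` is
rejected. Extra risk over the model background keeps the curve on the same
effect-metric scale as the AD analysis; background correction for stochastic
endpoints is a convention, not a settled question. The nested estimator is
verified against adaptive quadrature of the variability integral.

## Comparators (`assessment`)

* deterministic RfD = BMDL/100, with the BMDL taken as the 5th percentile
  of the pooled bootstrap BMD distribution (the lower one-sided 95% limit);
* linear extrapolation for tumor endpoints: BMDL at 10% extra risk scaled
  to a human equivalent by `(BW_animal/BW_human)^0.25`, then linear in
  incidence below 10%. When the assessment's `M*` is not 10%, the BMDL10 is
  recomputed from the stored bootstrap parameter vectors.

Reports round to 2 significant figures at print time only; intervals are
recomputed from the stored sample arrays whenever requested, so the printed
report can never drift from the underlying samples.

## Synthetic data and what passing tests show

`data_io.simulate_*` generate the study conditions used throughout the
tests and the acceptance script:

* continuous: a chronic-rat-style body-weight endpoint — exponential
  decrease from 400 g, 6 dose groups (0–200 mg/kg-day), 50 animals/group,
  within-group geometric CV 8% (typical for body weight);
* quantal: a chronic-mouse-style tumor endpoint — Weibull with 2%
  background, 4 dose groups (0–300 mg/kg-day), 50 animals/group, ~60%
  incidence at the top dose.

Individuals are lognormal about the model median with log-SD `ln(1+cv)`
(the exact relation `sqrt(ln(1+cv²))` agrees to second order). The
generators emulate group-summary reporting, monotone responses, and
binomial sampling; they do not emulate litter effects, time-to-tumor
censoring, dose measurement error, historical-control drift, or
non-monotone responses. Passing tests therefore demonstrate correctness of
the statistical machinery under its own assumptions, not robustness to
those real-data complications.

Problem sizes in the shipped tests and acceptance script are desk-scale
choices: 200–1000 bootstrap samples per model, 2×10⁵–10⁶ MC draws, and
2000-draw outer loops for population curves — enough for 2-significant-
figure stability of the reported percentiles, which is the reporting
precision.

## Degenerate inputs and numerical choices

* Empirical quantiles use linear interpolation throughout.
* BMD inversion brackets the smallest crossing on a 240-point geometric
  grid over (0, 10×max dose] and polishes with Brent's method at machine
  tolerance; no crossing raises a range error.
* Flat continuous data fit cleanly (effect ≈ 0) and fail downstream with
  the explicit range error rather than returning a pseudo-BMD.
* All-zero quantal counts fit at the parameter boundary and are flagged
  (`at_boundary`), not silently accepted.
* `σ_H = 0`, `I* = 0.5`, zero-spread adjustment distributions, and empty OU
  all collapse to the correct deterministic limits (tested).
* A GOF screen that rejects every candidate model aborts the assessment
  with a named error; the acceptance script responds by drawing a fresh
  synthetic study, which is the synthetic analogue of collecting new data.

## Known limitations

* Only two continuous and six quantal families; no covariate (study/sex)
  joint fitting, no Bayesian posterior sampling, no formal model-averaging
  weights (equal-weight pooling only).
* Severity is handled through a single cut point per dataset; ordinal
  multi-category data are out of scope.
* CSAF/DDEF and RDDR/RGDR values are user-supplied point inputs; deriving
  them from raw toxicokinetic or dosimetry data is out of scope.
* Extrapolation below `M*` or to very low incidences, and combination with
  exposure distributions, are not implemented.
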