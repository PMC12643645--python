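# Methods

This note documents the statistical and numerical choices inside `heatpm`:
what each stage assumes, which knobs matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Study design

The unit of analysis is a *stratum*: one person's outcome hospitalization
(case day) plus its time-stratified referents — all other dates in the same
calendar month and year sharing the case's weekday. Every month contains 4
or 5 occurrences of each weekday, so strata have 4 or 5 days (3 or 4
controls) before any exposure-completeness drops. Matching is
bidirectional: referents fall both before and after the case day.

Cohort eligibility mirrors a claims-based workflow:

1. *Qualifying admission*: first admission with a cohort-defining
   (dementia-related) diagnosis code among the first ten billing positions.
   The code list is an input; the synthetic generator uses stand-in codes.
2. *Outcome admission*: first warm-season (May 1 – September 30) admission
   at least 30 days after the qualifying admission, admitted from a
   non-healthcare facility, clinic referral or emergency room, not from a
   skilled nursing facility, and with no further admission within 30 days
   of its discharge. Candidates failing a filter are skipped and the search
   continues.

The 30-day washout anchors at the qualifying *admission* date by default;
the anchor is configurable (`EligibilityRules.washout_anchor="discharge"`)
because either reading is defensible. Outcome selection has two
implementations — a per-enrollee reference loop and a columnar vectorized
engine used by default — verified equal on generated cohorts; the
vectorized engine's readmission rule uses each admission's successor, which
is equivalent because admission dates are strictly increasing within an
enrollee (the generator enforces at most one admission per enrollee-day).

## Exposures

**Heat index.** Computed in °F internally (the NWS equations' native
scale), stored in °C. Below the 80 °F switch — precisely, when the average
of Steadman's simple formula and the temperature is < 80 °F — the simple
formula value is returned; otherwise the Rothfusz nine-coefficient
regression applies, minus the low-humidity adjustment (RH < 13%,
80–112 °F) or plus the high-humidity adjustment (RH > 85%, 80–87 °F). The
published algorithm is not exactly continuous at the switch: the seam is
under 1 °F for RH ≤ 50% but grows to ≈2.3 °F near saturation. We implement
the algorithm as published and test the seam at those documented bounds.
Daily maximum temperature is paired with daily minimum relative humidity,
the two inputs the gridded meteorology supplies.

**Climate-subtype percentiles.** Per Köppen–Geiger subtype, all
warm-season ZIP-day heat-index values over all years are pooled; the
percentile of a value is the right-continuous ECDF, 100·#{≤ x}/n, with ties
sharing a percentile and a nearest-rank inverse (quantile(0) = minimum,
quantile(100) = maximum, matching the 0–100 endpoint convention). The same
°C therefore maps to different percentiles in different climates —
acclimatization by construction.

**Grid-to-ZIP aggregation** is the unweighted mean of mapped grid-cell
values; polygon geometry is out of scope (the cell→ZIP mapping is an
input). **Moving averages** (the 3-day sensitivity analysis) are trailing
and calendar-aware: day *t* averages days *t, t−1, t−2* of the same ZIP,
missing if any lag is absent; an April run-in supplies the early-May lags.

## Bases and contrasts

B-splines are cubic, evaluated without an intercept column (the
conditional likelihood absorbs stratum intercepts; the convention matches
R's `splines::bs`). Internal knots sit at equally spaced quantiles of the
observed exposure; boundaries default to the observed min/max. For PM2.5
the pipeline caps the upper boundary at the observed 99th percentile:
evaluation clamps beyond the boundary, so the top 1% of days contribute at
the boundary value rather than supporting a spline tail. This both matches
the reporting convention (no inference beyond the 99th percentile of a
highly right-skewed exposure) and keeps the tensor crossbasis identifiable
— with boundaries at the raw maximum the corner basis functions are
supported by a handful of days and the conditional-logit likelihood is
near-flat in those directions.

The crossbasis concatenates the two marginal bases (df₁ + df₂ columns)
with their row-wise outer product flattened row-major (df₁·df₂ columns).
Every reported effect is a row-difference contrast c = x(target) −
x(reference); log OR = c'β, se = √(c'Vc), 95% CI with the 1.96 normal
multiplier. Contrasts are transitive and reference shifts leave pairwise
contrasts unchanged, so centering the basis would be equivalent. The
"marginal OR" in the linear interaction model (b₁H + b₂P + b₃HP) is
evaluated with the co-exposure held at a stated level — the observed median
by default, configurable, since a marginal effect is undefined under
interaction without such a choice; an alternative reading (averaging over
the co-exposure distribution) would replace the level by its mean, which
for this linear model gives the same value at `at = mean`.

## Conditional logistic fitting

The negative log-likelihood, analytic gradient and observed information
are computed with per-stratum log-sum-exp stabilization and segment
reductions (vectorized over all strata). Optimization is damped Newton: a
tiny relative ridge (10⁻¹⁰ of the mean Hessian diagonal, escalated only if
factorization fails), a step-norm cap of 5, and step-halving on the
likelihood. Convergence requires relative log-likelihood change < 10⁻¹⁰
and max |gradient| < 10⁻⁶. The covariance is the inverse observed
information at the optimum. A coefficient exceeding 15 in magnitude at
termination raises a separation diagnostic rather than returning a runaway
estimate: e¹⁵ is far beyond any interpretable odds ratio on these basis
scales, and complete separation (case day always at the stratum-maximal
exposure) drives coefficients through that bound with a still-nonzero
gradient. In the pipeline a separation in one menu model is recorded and
its report cells are marked absent; the other models proceed.

AIC is 2k − 2ℓ; df selection minimizes AIC with ties broken toward the
smaller df.

## Two-stage dependence analysis

Stage 1 is OLS of PM2.5 on an intercept plus a df-4 B-spline of the heat
exposure, pooled over all stratum-days (case and control alike — the
dependence is a property of the exposure process). Coefficient covariance
is σ²(X'X)⁻¹. Stage 2 evaluates the extreme-vs-median heat contrast in the
fitted interaction model with PM2.5 set to its stage-1 prediction at each
heat level. The Monte Carlo interval draws γ* ~ N(γ̂, V̂_γ) and β* ~
N(β̂, V̂_β) *independently* (an approximation — both models see overlapping
data; treating the draws as independent ignores their small covariance),
recomputes the contrast per iteration, and reports empirical 2.5/97.5
percentiles over 5,000 iterations. The point estimate is the plug-in
contrast at the fitted coefficients; the MC sample serves only for the
interval. With both covariances zero the interval collapses exactly onto
the plug-in value. Stage-1 weighting (by stratum vs by ZIP-day) was an
open choice; the unweighted pooled regression was adopted.

## Synthetic data generator

The generator supplies the structure the analysis depends on, under one
root seed with fixed per-operation child streams
(`SeedSequence([seed, op_key])`), so identical configurations reproduce
byte-identical tables.

* **Climate**: each synthetic ZIP gets one of the 18 Köppen–Geiger
  subtypes found in the contiguous US (guaranteed coverage when there are
  at least as many ZIPs as requested subtypes); subtype determines type
  (Arid/Continental/Temperate/Tropical) and a baseline warm-season
  temperature (22–31 °C).
* **Temperature**: baseline + seasonal sinusoid (amplitude 8 °C, peak near
  July 20) + AR(1) noise (ρ = 0.6, innovation sd 3 °C). Minimum relative
  humidity is Gaussian (mean 45%, sd 15%) clipped to [5, 100].
* **PM2.5**: exp(log link + ε), link = 2.0 + 0.30·tmax µg/m³ (floored at
  0.5), ε ~ N(0, 0.5²) on the log scale — strictly positive, right-skewed
  (lognormal skewness ≈ 1.75 at this sd) and positively coupled to heat.
  The defaults give a warm-season PM2.5 median near 10 and mean near
  12 µg/m³ and a mean heat index near 29 °C, the magnitudes of 2000–2016
  US ZIP-day panels.
* **Admissions**: every enrollee has ≥1 admission over the window
  (1 + Poisson(2)); a configurable fraction (default 0.9) carries a cohort
  code within the first ten diagnosis positions; skilled-nursing origins
  and non-qualifying admission sources are injected at configurable rates
  (defaults 5%); one fixed residential ZIP per enrollee (strata span one
  month, so within-stratum residence is constant regardless).
* **Case days**: within each stratum the case is drawn with probability
  proportional to exp(x_d'β_true) for a configurable basis and truth —
  the exact inverse of the conditional-logit model, so fits are validated
  by parameter recovery. The default truth is a linear heat-percentile
  effect with OR 1.015 per 49 percentile points (the extreme-vs-median
  contrast).

What the generator does *not* emulate: real US geography and spatial
correlation between ZIPs, wildfire episodes, humidity–temperature
dependence, multiple pollutants, seasonal admission rates, and mortality/
censoring. Passing tests therefore demonstrate the correctness and
calibration of the estimation machinery under a controlled truth, not the
epidemiological findings themselves — the restricted claims data those
require are out of reach by design.

## Problem sizes and numerical tolerances

Test and acceptance studies are sized to keep the full suite and the
acceptance script at a few minutes on one CPU while leaving the
statistical checks well-powered: parameter recovery uses 100 replicates of
50,000 strata; interaction recovery 50 replicates of 20,000; Monte Carlo
coverage 200 replicates of 6,000 strata at 5,000 iterations; AIC selection
50 replicates of 20,000. The acceptance script's pipeline run uses 190,000
enrollees (≈51,000 strata, roughly the scale at which spline tail
contrasts become informative). Spline-tail contrasts (the 99th-percentile
cell from df-4 fits) remain the noisiest quantities at these scales; their
intervals honestly reflect that.

Gradient correctness is held to 10⁻⁶ against central differences;
grid-search agreement to 2×10⁻³ (the oracle grid step); B-spline
polynomial reproduction to 10⁻⁸; group-mean aggregation to 10⁻¹².

## Known limitations

* The independence approximation in the two-stage Monte Carlo slightly
  misstates the interval when the two models' estimation errors correlate;
  simulated coverage at the study conditions is nonetheless within the
  nominal band.
* Weakly identified crossbasis corners at small cohort sizes (≲1,000
  strata) can trip the separation diagnostic; this is a small-sample
  identification problem, not a fitting defect, and disappears at study
  scale.
* Percentile tables assume the pooled warm-season sample is large enough
  that the ECDF granularity (100/n) is negligible.
* The eligibility engine treats overlapping admission intervals
  (discharge before admission) as malformed candidates and skips them.
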