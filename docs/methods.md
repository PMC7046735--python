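# Methods

## Photoperiod

Day length is the sunset-minus-sunrise interval in hours, computed with
the NOAA-style sunrise equation: solar declination and equation of time
from a low-order Fourier series in the fractional year, and the
sunrise/sunset hour angle H₀ from

cos H₀ = (cos 90.833° − sin φ sin δ) / (cos φ cos δ),

with day length = 2·H₀/15° hours. The 90.833° zenith folds in standard
atmospheric refraction (34′) and the solar half-diameter (16′);
geometric sunrise with standard refraction is assumed (civil twilight is
not used). When the equation has no solution the result is clamped to
0 h (polar night) or 24 h (polar day). Longitude is accepted in the
interface because residence coordinates arrive as (latitude, longitude)
pairs, but it shifts only clock times, not duration. The low-order
declination series errs by < 0.3°, i.e. well under a minute of day
length at temperate latitudes — negligible against the month-level
resolution of the seasonal models. Test oracles were frozen from an
independent ephemeris implementation (R `geosphere::daylength`); the two
agree to well under five minutes in the UK latitude band.

## Cosinor model

For outcome y (a volume, mm³) and month of scan M ∈ {1..12}:

y = μ + β·cos(2π(M−1)/12) + γ·sin(2π(M−1)/12) + covariates + ε,

fitted as a Gaussian GLM with heteroskedasticity-robust (HC1) sandwich
standard errors; age and TBV are the default adjustment set. January is
the phase origin, so β > 0 alone peaks in January and γ > 0 alone in
April.

* Amplitude A = √(β² + γ²): half the peak-to-trough range of the fitted
  sinusoid. Its SE comes from the delta method on the robust (β, γ)
  covariance; "amplitude > 0" is a one-sided Wald test.
* Acrophase φ = 12·angle/(2π) + 1 with angle = atan2(γ, β) wrapped to
  [0, 2π). The single-argument arctangent of γ/β cannot reach the
  quadrants with β < 0 that summer peaks produce, so the two-argument
  form is used. φ lives in [1, 13); the month label rounds φ half-up and
  wraps to 1–12. Because the rounding convention for published labels is
  not standardised, label comparisons should tolerate ±1 month; the
  continuous φ is always reported alongside.
* Seasonality verdict: (p_β < α or p_γ < α, default α = 0.025) **and**
  amplitude significantly > 0 at the same one-sided level **and**
  ΔAIC = AIC(full) − AIC(covariates-only) < 0. Both criteria are
  required; the AIC comparison uses the same covariates in both models.

## Count models for symptom scores

The four symptom items are 0–3 frequency codes and the total score is
their 0–12 sum. They are treated as unbounded counts — the convention
for overdispersed PHQ-style items — via NB2 negative-binomial regression
(variance μ + αμ²) with log link, maximum-likelihood dispersion α, HC1
robust SEs, and IRR = exp(b). The ceiling at 3 is a property of the
instrument, not the model; its effect is confined to the generator
(below). When a fixed dispersion of 0 is requested the Poisson model is
fitted instead (the NB2 boundary limit, also used as a fallback when the
ML dispersion collapses to the boundary).

Overdispersion is assessed by the raw variance/mean ratio together with
a likelihood-ratio test of NB2 against the nested Poisson model; since
the dispersion sits on the boundary under the null, the p-value uses the
½·χ²(1) mixture. The verdict requires both the test to reject and the
ratio to exceed 1.

Separation guard: an indicator level whose members all have zero counts
(common for rare ethnicity categories in bootstrap resamples) has an
unbounded ML coefficient; such columns, and indicator levels absent from
a resample, are dropped from the design for that fit and reported as
NaN. Coefficients of interest (continuous exposures/mediators) are never
affected.

Hierarchical volume–photoperiod regression enters covariate blocks in
order (age, then TBV), then photoperiod; it reports photoperiod's B
(mm³/hour), SE, p, the incremental R² attributable to photoperiod, and
r = sign(B)·√(incremental R²) as the standardized association.
Bonferroni adjustment is α/m with the study's families m = 15
(photoperiod–symptom) and m = 75 (volume–symptom).

## Mediation and the BCa bootstrap

The three-variable path model fits: a (mediator on exposure, OLS with
robust SEs), b and c′ (outcome on mediator and exposure jointly, NB2),
and c (outcome on exposure without the mediator). The indirect effect is
the product a·b of full-sample estimates. An identity-link Gaussian mode
exists as an oracle in which c = c′ + a·b holds exactly; under the NB
log link the decomposition is only approximate and is not asserted.

Eligibility (the classical requirements): a significant, b significant,
and attenuation |c′| < |c|. Whether the direct effect also loses
significance is reported but not required — with large samples a genuine
partial mediation retains a significant c′, so requiring
non-significance would make eligibility an artifact of sample size.

BCa bootstrap: participants are resampled with replacement; a and b are
refit per resample. The bias-correction constant z₀ is Φ⁻¹ of the
fraction of resampled estimates below the point estimate (ties counted
half); the acceleration comes from the jackknife skewness
a = Σd³ / (6(Σd²)^{3/2}) with d the deviations of leave-group-out
estimates. A delete-group jackknife (default 100 groups, assigned by row
index modulo the group count) replaces leave-one-out at large n; for the
smooth, asymptotically linear product statistic the grouped influence
values estimate the same skewness at a fraction of the cost. The
bootstrap p-value is defined as the smallest 1 − level at which the BCa
interval excludes zero, computed in closed form by inverting the BCa
quantile map at zero. Everything is deterministic given the seed, and a
run aborts if more than 10% of resamples fail to fit.

Performance: resample refits use a dedicated warm-start Newton solver
for the NB2 likelihood (block Newton on the coefficients alternating
with a 1-D Newton step on log α, started at the full-sample optimum).
It reproduces the statsmodels optimum to ~1e−14 (pinned by a unit test);
all reported standard errors and p-values still come from statsmodels
fits.

Known behaviour: under the joint null a = b = 0 the product statistic is
well known to be conservative (rejection far below nominal), because the
product of two independent near-zero estimates concentrates at zero
faster than any normal approximation. Type-I calibration is therefore
checked under the single-path null (a = 0, b ≠ 0), where the indirect
effect is truly zero and near-nominal rejection is attainable.

## Synthetic cohort generator

The generator emulates a single-site population-imaging cohort table.
Defaults are calibrated to the published cohort characteristics: n =
9 289 with 51.8% females; ages 44–79 (truncated normal, mean 62.4, SD
7.4); scan dates uniform over May 2014–December 2016; residence latitude
uniform in a 53.0–53.9° band around the scanning centre; ethnicity and
urban/rural proportions, Townsend scores, TBV/GMV/WMV and brainstem
volume means from the cohort's descriptive table; symptom-item means per
sex (e.g. female low mood 0.24) set the count-model intercepts.

Volumes: each substructure s (midbrain, pons, medulla, SCP) is

mean_s + A_s·cos(2π(M−1)/12 − θ₀) + a_s·(photoperiod − 13 h)
 + age-slope_s·(age − 62.4) + TBV-slope_s·(TBV − 1125.9) + N(0, σ_s),

and the whole brainstem is the **sum of the four substructures** plus
its own extra terms and noise — the published substructure means sum to
the whole-brainstem mean to 0.1 mm³, and the construction guarantees the
substructure < whole invariant by design. Photoperiod is itself a
sinusoid of season, so a nonzero photoperiod path a_s alone already
produces a seasonal volume rhythm; to avoid double-counting, the
explicit cosine amplitudes A_s default to 0 and the defaults drive
seasonality entirely through the photoperiod paths, set to the published
volume-per-hour slopes (whole ≈ 105.5 mm³/h as the sum of part slopes).
Residual SDs are set so the cosinor robust SEs come out on the published
scale (e.g. ≈ 33 mm³ for the whole-brainstem cosine coefficient at full
n). Gaussian residuals are assumed — the noise model the linear/cosinor
analyses imply; nothing heavier-tailed is emulated.

Symptoms: item counts are gamma-Poisson (NB2, default dispersion α = 0.8,
back-solved from the published low-mood mean/SD via var = μ + αμ²) with
log-link mean

log μ = log(item mean per sex) + c′_sex·(photoperiod − 13) + b_sex·(V − V̄),

where V is the configured mediator volume (whole brainstem by default)
and the photoperiod/volume terms apply to the configured affected items
(low mood and anhedonia). Path coefficients are sex-specific; defaults
give females b = −4.7×10⁻⁵ per mm³ and c′ = −0.023 per hour (the
published female coefficient scale) and males zero — the female-only
mediation structure. Counts are then clipped to the 0–3 item range; at
the calibrated means the clip probability is ≈ 10⁻³, so the NB fits
remain essentially well specified. The truth object records the derived
cosinor coefficients (β = A·cosθ₀, γ = A·sinθ₀) and the true indirect
effect a·b per sex (defaults: female ≈ −0.0050).

What the generator does **not** emulate: correlated residuals between
structures beyond the sum construction, missing data, scanner drift,
geography beyond a latitude band, longitudinal change, or reporting
biases. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated data-generating model, not robustness to
those real-data features.

## Simulation sizes

Monte-Carlo checks use sizes chosen to keep the default test run fast
while leaving calibration statements statistically meaningful: cosinor
null calibration 1 000 fits at n = 120; NB null calibration 500 fits at
n = 400; BCa coverage and type-I 120 replicate datasets each at
n = 2 000 with 999 resamples and a 50-group jackknife; parameter
recovery at n = 5 000. Coverage bands in the tests are nominal ± 4
percentage points, consistent with the binomial Monte-Carlo error of
those replicate counts.

## Pipeline

`run_study` applies, per group (all, female, male): descriptives;
cosinor fits for the five structures (age + TBV adjusted); NB
photoperiod→symptom models (age, ethnicity, living area, Townsend);
hierarchical volume–photoperiod models; NB volume→symptom models (adding
TBV); and, only for mediator/outcome pairs passing the requirements
checklist, the BCa bootstrap — reproducing the selective reporting of a
requirements-gated mediation table. Participant exclusions run image
quality first, then mood completeness, each participant counted once.
Bootstrap seeds are spawned deterministically from the run seed and the
(group, mediator, outcome) indices; identical configurations produce
byte-identical CSV bundles. The run log records the seed, the SE flavour
(HC1) and the alpha levels.
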