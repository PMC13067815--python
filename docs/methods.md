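# Methods

`harescape` quantifies how a prey species distributes risk-avoidance
behavior along three axes — time of day, space, and movement — and ships a
synthetic-data generator so that every estimator in the pipeline can be
validated by parameter recovery. This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic tests do and do not establish about field data.

## Solar bookkeeping

Sunrise/sunset and civil dawn/dusk come from the NOAA low-accuracy solar
ephemeris (trigonometric series for declination and the equation of time).
Event times are found by a 1-minute altitude scan with linear refinement,
which handles the two altitude thresholds (−0.833° for sunrise/sunset,
−6° for civil twilight) uniformly; accuracy is within about ±2 minutes of
almanac values for mid- and high-latitude, non-polar sites. Polar
day/night is out of scope and rejected at construction (|latitude| < 66.5°).

*Night* is defined as civil dusk to the next day's civil dawn. This is the
definition used everywhere downstream (night windows for AUC ratios, daily
nocturnality, diel phase of steps).

The solar-time transform is double-anchored: each day's clock times are
mapped piecewise-linearly so that the day's sunrise lands on the
study-period mean sunrise and its sunset on the mean sunset, stretching the
day and night segments independently. This removes the seasonal drift in
day length before circular density estimation. The averaging window for
the anchors defaults to the dates present in the data and is configurable.
The ephemeris year is anchored to each site's first study winter;
sensitivity across years is below one minute.

## Landscape

Rasters live on a shared planar 30-m grid and are stored as plain gridded
text with a JSON header. The vector ruggedness measure follows Sappington:
Horn 3×3 slope/aspect, unit terrain normals, and 1 − |resultant|/n over a
moving window (default 3×3, configurable; the window size is a free choice
here). Border gradients use linear extrapolation so uniformly inclined
planes are exactly flat (VRM = 0). Buffer extraction uses a
cell-center-in-circle membership rule — deterministic and unambiguous where
partial-cell handling would otherwise be undefined. For simulation and
step-covariate assembly the same rule is precomputed at every cell by
convolution with the disc footprint, which is exactly equivalent and
removes a quadratic bottleneck.

## Synthetic data

The generator is first-class, tested code; its defaults are the study
conditions of the recovery tests.

* **Landscape**: Gaussian random fields by spectral synthesis (FFT with a
  Gaussian transfer function; correlation length 4 cells by default), with
  cover classes obtained by thresholding a correlated field at quantiles
  (0.30/0.55/0.80 → open/conifer/deciduous/mixed). Spectral synthesis keeps
  the long-correlation limit clean: layers tend to constants and VRM to 0.
* **Activity**: per-minute Bernoulli states whose logit follows a
  two-component von Mises mixture over solar time (crepuscular peaks at 19 h
  and 5 h solar, κ = 2 each), a moonlight slope applied at night (−0.5 per
  unit moon fraction), a day-minus-night temperature-difference slope
  applied in daytime (+0.3 per ~3 °C), and a per-hare random intercept
  (SD 0.3). Minute resolution is sufficient for daily nocturnality and
  KDE; raw accelerometer signals are not simulated.
* **Weather/moon**: AR(1) hourly temperature with a diurnal harmonic,
  bounded-random-walk snow depth (≥ 0), and a 29.53-day sinusoidal moon
  fraction. The moon is a phase model, not an ephemeris — the analysis only
  consumes a nightly [0, 1] fraction.
* **Tracks**: exact finite-proposal step-selection simulation: from each
  position, 50 proposals from the tentative kernel (gamma lengths, von
  Mises turns), one selected with probability ∝ exp(βᵀz) where z are
  grid-standardized 50-m buffered covariates at the proposal endpoint.
  Defaults: gamma(shape 2, scale 40 m), κ = 0.5, β = (+0.5 canopy,
  −0.4 tree density, +0.6 conifer proportion) per grid SD. About 5 % of
  fixes get HDOP > 5 and 2 % < 3 satellites so the filters are exercised.
  Out-of-extent proposals are reflected.
* **Detections**: occupancy state per site from ψ(site covariates),
  detections from p(site covariates, survey weather, site random
  intercept). Defaults ψ: intercept 0.3, +0.5 canopy; p: intercept −0.8,
  +0.4 tree density, −0.3 snow; site intercept SD 0.5.

What passing recovery tests show: the estimators are consistent and their
uncertainty honest *under the generating model* — correctly classified
states, no GPS positional error beyond the flagged rows, habitat effects
that are log-linear in the buffered covariates, independent detections.
They do not establish robustness to behavioral-classification error,
autocorrelated detection, or misspecified habitat functional forms.

## Diel activity

The circular KDE is a von Mises kernel mixture evaluated on a fixed
512-point grid and renormalized to integrate to 1 (trapezoidal error is far
below reporting precision). The smoothing concentration follows the
Ridout–Linkie plug-in rule, κ_bw = [3 n κ̂² I₂(2κ̂) / (4 √π I₁(κ̂)²)]^{2/5}
with κ̂ the ML von Mises concentration, times a `bw_adjust` factor
(default 1). Window integrals treat the grid as periodic piecewise-linear
and are computed exactly, so complement- and window-additivity identities
hold to machine precision and Δ = 1 for identical densities.

The nocturnality index is the density mass inside the night window
(AUC_night/AUC_24h); overlap is ∫ min(d₁, d₂) over a window. Confidence
intervals use the smoothed bootstrap (resample with replacement, add von
Mises noise at κ_bw — equivalent to sampling the KDE), 1000 replicates by
default, percentile 2.5/97.5.

Daily nocturnality divides a hare-day's active minutes falling at night by
its total active minutes; a minute is nocturnal when it precedes its
calendar day's civil dawn or follows its civil dusk. Days with under 20 h
of recorded states (threshold configurable) or zero activity are dropped
and logged — short days would otherwise bias the ratio. Active minutes
entering the KDE are thinned to one sample per 15 minutes of continuous
activity to reduce serial dependence; both choices are configurable because
no external convention fixes them.

## Nocturnality GLMM

Daily nocturnality is modeled with a beta likelihood: logit link for the
mean, shared precision φ, per-hare random intercept. Boundary responses use
the Smithson–Verkuilen transform y′ = (y(n−1) + 0.5)/n. The candidate set
holds main effects {site, temperature difference, moonlight, Julian date}
in all 8 models and varies the subsets of the three environment-by-site
interactions (sizes 0–3). Julian day is kept as the covariate (a proxy for
night length) rather than replaced by computed night length. φ is constant
(no dispersion covariates).

The random intercept is marginalized by **adaptive** Gauss–Hermite
quadrature (15 nodes): nodes are centered at each hare's posterior mode and
scaled by the local curvature. Adaptivity is essential, not cosmetic — with
~80 observations per hare the integrand is an order of magnitude narrower
than the random-effect prior, and a fixed rule visibly biases the
site-level contrasts and understates their standard errors. Optimization is
L-BFGS-B on (β, log φ, log σ) with the analytic fixed-rule gradient; the
rule is refreshed between rounds until the estimates are stable. Standard
errors come from a finite-difference Hessian of the adaptive objective. The
implementation is cross-checked in the test suite against an independent
mixed-model fit (glmmTMB via Rscript) when R is available.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects plus φ and
σ; Akaike weights normalize exp(−Δ/2).

## Step selection

Fix hygiene retains HDOP ≤ 5 and ≥ 3 satellites (boundaries inclusive).
Regularization is a greedy earliest-in-window pass per hare×winter: from
the current anchor, the next step ends at the earliest fix whose gap lies
within 4 ± 2 h; when none qualifies the anchor advances and the track
fragments, resetting turn angles.

The tentative kernel is a gamma MLE on step lengths and a zero-mean von
Mises MLE on turn angles, fitted per hare×winter so bootstrap regeneration
is unit-consistent (a pooled variant is available). Each observed step with
a defined turn angle anchors a stratum of 1 observed + 10 random steps
drawn from the tentative kernel about the previous bearing.

The conditional logistic likelihood (per-stratum softmax) is maximized by
Newton–Raphson with analytic gradient and Hessian, with step-halving,
detection of stratum-constant covariates (dropped with a warning — they
carry no information), and a divergence guard (‖β‖ > 50 flags separation).
The implementation is cross-checked against `survival::clogit` in the test
suite. Habitat and environmental covariates are z-scored over all cases
pooled — recomputed inside every bootstrap replicate — while the movement
terms logSL and cosTA stay on their natural scale: the selection-free
updates k* = k₀ + β_logSL + Σ β_(logSL×e)·e and κ* = κ₀ + β_cosTA + … are
only meaningful with unscaled movement terms, with environment values e in
SD units (0 = average conditions). The gamma scale is left untouched (no
linear-SL term in the models).

The per-individual bootstrap resamples 25 (night) or 15 (day) observed
steps with replacement from each hare×winter unit meeting the matching
inclusion threshold, regenerates the 10 random steps from the unit's
tentative kernel, refits every candidate, and averages AICc weights; the
top model is the one with the largest mean weight and its replicate
coefficients give percentile 95 % CIs. Replicate coefficients are recorded
on the natural covariate scale so they are comparable across replicates
whose internal standardizations differ. Candidate sets are the base model
(all landscape mains + the fixed movement component) plus one or two 2-way
interactions from a configured pool; the pool is config data because no
external source fixes it. The diel phase of a step follows its start time
under the civil-twilight definition.

## Occupancy

Detection histories are site×survey 0/1/NA matrices over consecutive
14-day windows anchored at Jan 1 and capped at April 30; trailing windows
shorter than 7 days are dropped; cameras inactive in a window give NA.
Species can be pooled into guilds by a mapping (e.g. coyote ∪ fox → canid)
before assembly. Each camera×winter is a distinct site (single-season
models; no closure assumption is invoked — detection is read as activity
intensity).

The marginal likelihood per site is ψ·E_b[∏ p^y (1−p)^{1−y}] + (1−ψ)·1[no
detections], with a site random intercept inside p's logit integrated by
Gauss–Hermite quadrature (15 nodes; here a fixed rule is adequate because
the per-site detection information is weak). The three ψ structures are
constant; year; year + all landscape covariates, compared by AICc with the
p structure held fixed. The fit is verified against brute-force grid
maximization and direct numerical integration in the tests.

The MacKenzie–Bailey statistic sums (O−E)²/E over detection-history
patterns, cohorted by missingness pattern; its null distribution comes from
a parametric bootstrap that simulates from the fitted model and refits each
replicate. c-hat is observed/mean-bootstrap; standard errors are inflated
by √c-hat when c-hat > 1 and CIs recomputed as ±1.96·SE on the link scale.

## Problem sizes and numerical choices

Recovery experiments in the test suite run at: step selection — 50
replicates of 20 hares × 100 steps with a 200-replicate bootstrap;
occupancy — 300 sites × 10 surveys, 100-replicate GOF bootstrap; beta
GLMM — 40 hares × 80 days, 50 replicate datasets for model identification.
The end-to-end synthetic study defaults to three small sites so a full run
stays interactive. Tolerances: density integrals to 1e−6, oracle
agreements to 1e−3 (quadrature) or 1e−4 (grid search), recovery at ±2 SE
or 95 % CI coverage.

Degenerate inputs are explicit errors, not NaNs: no solar event, polar
latitude, zero-length diel windows, degenerate step-length samples,
even/small VRM windows, overlapping camera deployments, strata without a
unique observed case. Singular random-effect fits (σ → 0) are reported as
zero, not errors.

## Known limitations

* The lunar covariate is a phase sinusoid; studies needing true lunar
  altitude or rise/set must substitute an ephemeris.
* The SSF sampler is finite-proposal (M = 50 by default); it approximates
  the exact selection density, converging as M grows.
* No zero/one-inflation in the beta GLMM beyond the boundary transform; no
  temporal autocorrelation structure in activity or detection.
* Mixed-effects (random-slope) step selection and multi-season occupancy
  dynamics are out of scope.
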