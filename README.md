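# harescape

Tools for quantifying how a prey species avoids predation risk along three
behavioral axes, built for winter studies of snowshoe hares (*Lepus
americanus*) and their predators but applicable to any collared prey +
camera-surveyed predator design:

* **Diel activity** — von Mises kernel densities of activity over solar
  time, the nocturnality index AUC_night/AUC_24h, hare–predator activity
  overlap Δ = ∫ min(d₁, d₂) within night/day windows, smoothed-bootstrap
  CIs, and a beta GLMM (logit mean, precision φ, hare random intercept
  marginalized by adaptive Gauss–Hermite quadrature) for daily nocturnality
  as a function of site, day−night temperature difference, moonlight, and
  Julian date, with an 8-model AICc candidate set.
* **Space use** — integrated step selection analysis (iSSA) for the prey:
  strata of 1 observed + 10 random steps (gamma step lengths × von Mises
  turn angles), conditional logistic regression maximizing
  Σ[βᵀx_obs − log Σ_alt exp(βᵀx_alt)], a per-individual bootstrap with
  AICc-weight model choice; single-season occupancy models (ψ, p) with a
  site random intercept, MacKenzie–Bailey goodness of fit, and √c-hat SE
  inflation for the predators.
* **Movement** — selection-free step-length and turn-angle kernels obtained
  by adding the fitted movement coefficients to the tentative kernel:
  k* = k₀ + β_logSL + Σ β_(logSL×e)·e, κ* = κ₀ + β_cosTA + β_(cosTA×snow)·snow.

A synthetic-data module generates every input the pipeline consumes —
activity records, GPS tracks governed by a known step-selection function,
camera detection histories, landscape rasters, weather and moonlight — from
explicit truth parameters, so each estimator is verified by parameter
recovery. Astronomical bookkeeping (sunrise/sunset, civil twilight, night
length, the double-anchored solar-time transform) is built in.

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

```python
import datetime as dt
import numpy as np
from harescape import SiteLocation, night_length, night_window
from harescape import synthetic_data as syn, diel_activity as da, step_selection as ssel
from harescape.solar_clock import to_solar_time
from harescape.pipeline import median_of_kernel

wi = SiteLocation("wisconsin", 45.0, -91.0, -6.0)
print("night:", round(night_length(wi, dt.date(2022, 1, 1)), 2))

# diel axis: activity from a known crepuscular truth, then the index
activity, _ = syn.gen_activity(syn.ActivityTruth(), n_hares=4, n_days=10,
                               seed=7, site=wi)
sub = da.subsample_active_minutes(activity)
angles = to_solar_time(sub["timestamp"].tolist(), wi)
night = night_window(wi, dt.date(2022, 1, 5))
idx = da.nocturnality_index(angles, night, n_boot=200, seed=1)
print("nocturnality: %.3f  [%.3f, %.3f]" % (idx.estimate, idx.ci_lo, idx.ci_hi))

# space/movement axes: tracks from a known SSF, recovered by the bootstrap
stack = syn.gen_landscape(3, (96, 96))
truth = syn.SsfTruth()   # beta = +0.5 canopy, -0.4 tree density, +0.6 conifer (per grid SD)
fixes, info = syn.gen_tracks(truth, stack, n_hares=8, n_steps=80, seed=11)
steps = ssel.regularize(ssel.filter_fixes(fixes))
base = sorted(truth.betas) + ["log_sl", "cos_ta"]
boot = ssel.bootstrap_ssf(steps, stack, [base], n_boot=100, n_obs=25, seed=5)
tent = ssel.fit_tentative(steps)
terms = [t for t in base if t in boot.coef_mean]
fit = ssel.SsfFit(terms=terms, coefs=np.array([boot.coef_mean[t] for t in terms]),
                  loglik=np.nan, aicc=np.nan, n_strata=0)
kern = ssel.selection_free_kernel(fit, tent)
print("selection-free median step: %.1f m" % median_of_kernel(kern)[0])
```

Output:

```
night: 14.04
nocturnality: 0.594  [0.583, 0.597]
selection-free median step: 66.9 m
```

The night at 45° N on January 1 lasts 14.04 h (civil dusk to next civil
dawn). The synthetic hares put 59 % of their activity into that night —
the crepuscular truth used here spreads activity across dusk and dawn
peaks, and the tight CI reflects 4 hares × 10 days of minute-level data.
The bootstrap covers the generating habitat coefficients (e.g. conifer
proportion +1.80 with CI [+1.31, +2.31] against a truth of +1.81 on the
raw-proportion scale), and the selection-free gamma kernel gives the
median step length under average environmental conditions.

Command-line equivalents: `harescape simulate | diel | nocturnality | ssf |
occupancy | report` (see `harescape --help`).

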