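"""Synthetic study generator with known ground truth.

Every input the pipeline consumes — activity sequences, GPS tracks, camera
detection histories, landscape rasters, weather, and moonlight — can be
generated here from explicit truth parameters, so each inference stage
(circular KDE and nocturnality, beta GLMM, integrated step selection,
occupancy) has a parameter-recovery test against the values that produced
the data.

Truth scales
------------
Step-selection coefficients (``SsfTruth.betas``) are expressed per standard
deviation of the corresponding 50-m buffered layer *over the whole grid*;
``grid_scaling`` on the generated track table records the grid means/SDs so
recovered coefficients (standardized within the sampled cases) can be
mapped back. Occupancy coefficients are on the logit scale against
grid-standardized 100-m buffer covariates.

All generators are deterministic per seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, i0

from .landscape import LandscapeStack, buffered_layers, compute_vrm
from .solar_clock import SiteLocation, solar_events

TWO_PI = 2.0 * np.pi
SYNODIC_MONTH = 29.53  # days


@dataclass
class ActivityTruth:
    """Diel intensity (two von Mises bumps at crepuscular peaks) + modifiers.

    ``peak_hours`` are solar hours of the two activity peaks (dusk-side and
    dawn-side); logit of the per-minute active probability is
    ``base + gain * mixture_density(theta) + moon_slope * moon * night
    + tempdiff_slope * tempdiff_z * day + hare_intercept``.
    """

    peak_hours: tuple[float, float] = (19.0, 5.0)
    kappas: tuple[float, float] = (2.0, 2.0)
    weights: tuple[float, float] = (0.5, 0.5)
    base: float = -2.0
    gain: float = 10.0
    moon_slope: float = -0.5
    tempdiff_slope: float = 0.3
    hare_sd: float = 0.3
    site: str = "synthetic"

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if min(self.kappas) < 0:
            raise ValueError("kappas must be >= 0")

    def mixture_density(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        out = np.zeros_like(theta)
        for h, k, w in zip(self.peak_hours, self.kappas, self.weights):
            mu = h * TWO_PI / 24.0
            out += w * np.exp(k * np.cos(theta - mu)) / (TWO_PI * i0(k))
        return out


@dataclass
class SsfTruth:
    """Habitat-selection coefficients and the tentative movement kernel."""

    betas: dict[str, float] = field(
        default_factory=lambda: {"canopy": 0.5, "tree_density": -0.4,
                                 "prop_conifer": 0.6})
    shape: float = 2.0       # gamma k0
    scale: float = 40.0      # gamma theta0, meters
    kappa: float = 0.5       # von Mises concentration of turn angles

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class OccTruth:
    """Occupancy (psi) and detection (p) logit coefficients."""

    psi_coefs: dict[str, float] = field(
        default_factory=lambda: {"(Intercept)": 0.3, "canopy": 0.5})
    p_coefs: dict[str, float] = field(
        default_factory=lambda: {"(Intercept)": -0.8, "tree_density": 0.4,
                                 "snow": -0.3})
    site_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.site_sd < 0:
            raise ValueError("site random-effect SD must be >= 0")


# ---------------------------------------------------------------------------
# landscape

def _grf(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    """Gaussian random field, unit variance, Gaussian spectral filter.

    Spectral synthesis (FFT of white noise shaped by a Gaussian transfer
    function) keeps the long-correlation limit clean: as ``corr_len`` grows
    the field tends smoothly to a constant.
    """
    if corr_len <= 0:
        raise ValueError("correlation length must be > 0")
    w = np.fft.fft2(rng.standard_normal(shape))
    ky = np.fft.fftfreq(shape[0])[:, None]
    kx = np.fft.fftfreq(shape[1])[None, :]
    filt = np.exp(-2 * np.pi**2 * corr_len**2 * (kx**2 + ky**2))
    z = np.real(np.fft.ifft2(w * filt))
    sd = z.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (z - z.mean()) / sd


def gen_landscape(seed: int, size: tuple[int, int] = (128, 128),
                  corr_len: float = 4.0,
                  class_quantiles: tuple[float, float, float] = (0.3, 0.55, 0.8),
                  elev_amplitude: float = 60.0,
                  cell_size: float = 30.0) -> LandscapeStack:
    """Random landscape stack: GRF continuous layers + thresholded cover.

    ``class_quantiles`` split a correlated field into open / conifer /
    deciduous / mixed in that order; VRM is derived from the elevation layer
    with the default 3x3 window.
    """
    if min(size) < 32:
        raise ValueError("landscape must be at least 32x32 cells")
    rng = np.random.default_rng(seed)
    canopy = np.clip(50 + 25 * _grf(rng, size, corr_len), 0, 100)
    tree = np.exp(6.0 + 0.5 * _grf(rng, size, corr_len))
    elevation = 500.0 + elev_amplitude * _grf(rng, size, corr_len * 2)
    cfield = _grf(rng, size, corr_len)
    edges = np.quantile(cfield, class_quantiles)
    cover = np.digitize(cfield, edges)  # 0 open, 1 conifer, 2 deciduous, 3 mixed
    vrm = compute_vrm(elevation, window=3, cell_size=cell_size)
    return LandscapeStack(
        grids={"cover_class": cover, "canopy": canopy, "tree_density": tree,
               "elevation": elevation, "vrm": vrm},
        origin=(0.0, 0.0), cell_size=cell_size)


def gen_lines(seed: int, stack: LandscapeStack, n_lines: int = 4):
    """Random straight 'linear features' (trails/roads) across the extent."""
    from shapely.geometry import LineString
    from shapely.ops import unary_union

    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = stack.extent()
    lines = []
    for _ in range(n_lines):
        if rng.random() < 0.5:
            lines.append(LineString([(xmin, rng.uniform(ymin, ymax)),
                                     (xmax, rng.uniform(ymin, ymax))]))
        else:
            lines.append(LineString([(rng.uniform(xmin, xmax), ymin),
                                     (rng.uniform(xmin, xmax), ymax)]))
    return unary_union(lines)


# ---------------------------------------------------------------------------
# weather & moon

def gen_weather(n_days: int, seed: int, start: _dt.date = _dt.date(2022, 1, 1),
                temp_mean: float = -8.0, temp_sd: float = 6.0,
                temp_ar: float = 0.95, diurnal_amp: float = 4.0,
                snow_start: float = 20.0) -> pd.DataFrame:
    """Hourly weather: AR(1) temperature with a diurnal cycle, wind,
    bounded-random-walk snow depth (cm, >= 0), sinusoidal moon fraction."""
    rng = np.random.default_rng(seed)
    n = n_days * 24
    eps = rng.standard_normal(n) * temp_sd * np.sqrt(1 - temp_ar**2)
    ar = np.empty(n)
    ar[0] = rng.standard_normal() * temp_sd
    for i in range(1, n):
        ar[i] = temp_ar * ar[i - 1] + eps[i]
    hours = np.arange(n) % 24
    temp = temp_mean + ar + diurnal_amp * np.sin(TWO_PI * (hours - 9) / 24.0)
    wind = np.maximum(0.0, 3.0 + 2.0 * rng.standard_normal(n))
    snow_daily = np.maximum.accumulate(np.zeros(n_days)) + snow_start
    walk = np.cumsum(rng.normal(0, 1.5, n_days))
    snow_daily = np.maximum(0.0, snow_start + walk)
    day_idx = np.arange(n) // 24
    moon_daily = 0.5 * (1 + np.sin(TWO_PI * np.arange(n_days) / SYNODIC_MONTH))
    ts = [
        _dt.datetime.combine(start, _dt.time()) + _dt.timedelta(hours=int(h))
        for h in range(n)
    ]
    return pd.DataFrame({
        "timestamp": ts, "temp": temp, "wind": wind,
        "snow": snow_daily[day_idx], "moon": moon_daily[day_idx]})


# ---------------------------------------------------------------------------
# activity

def _day_solar_theta(site: SiteLocation, date: _dt.date, minutes: np.ndarray,
                     anchors: tuple[float, float],
                     cache: dict) -> np.ndarray:
    """Vectorized double-anchored solar angle for one day's minute grid."""
    def ev(d):
        if d not in cache:
            cache[d] = solar_events(site, d)
        return cache[d]

    mean_rise, mean_set = anchors
    e = ev(date)
    nxt_rise = ev(date + _dt.timedelta(days=1)).sunrise + 24.0
    prev_set = ev(date - _dt.timedelta(days=1)).sunset - 24.0
    h = minutes / 60.0
    sh = np.empty_like(h)
    day = (h >= e.sunrise) & (h < e.sunset)
    eve = h >= e.sunset
    mor = ~day & ~eve
    sh[day] = mean_rise + (h[day] - e.sunrise) / (e.sunset - e.sunrise) * (
        mean_set - mean_rise)
    sh[eve] = mean_set + (h[eve] - e.sunset) / (nxt_rise - e.sunset) * (
        mean_rise + 24.0 - mean_set)
    sh[mor] = mean_set - 24.0 + (h[mor] - prev_set) / (e.sunrise - prev_set) * (
        mean_rise + 24.0 - mean_set)
    return (sh % 24.0) * TWO_PI / 24.0


def gen_activity(truth: ActivityTruth, n_hares: int, n_days: int, seed: int,
                 site: SiteLocation | None = None,
                 start: _dt.date = _dt.date(2022, 1, 1),
                 use_solar_time: bool = True):
    """Per-minute active/inactive records + matching weather table.

    Returns ``(activity, weather)`` data frames. Activity states are
    Bernoulli draws whose logit follows the diel intensity (evaluated in
    solar time when a site is given), a moonlight term applied at night, a
    day-minus-night temperature-difference term applied in daytime, and a
    per-hare random intercept.
    """
    if n_hares < 1 or n_days < 1:
        raise ValueError("n_hares and n_days must be >= 1")
    rng = np.random.default_rng(seed)
    weather = gen_weather(n_days, seed + 1, start=start)
    minutes = np.arange(1440.0)
    cache: dict = {}
    if site is not None and use_solar_time:
        dates = [start + _dt.timedelta(days=i) for i in range(n_days)]
        evs = [solar_events(site, d) for d in dates]
        anchors = (float(np.mean([e.sunrise for e in evs])),
                   float(np.mean([e.sunset for e in evs])))
    hare_eff = rng.normal(0, truth.hare_sd, n_hares)

    temp = weather["temp"].to_numpy().reshape(n_days, 24)
    moon_daily = weather["moon"].to_numpy().reshape(n_days, 24)[:, 0]

    frames = []
    base_dt = _dt.datetime.combine(start, _dt.time())
    for d in range(n_days):
        date = start + _dt.timedelta(days=d)
        if site is not None and use_solar_time:
            theta = _day_solar_theta(site, date, minutes, anchors, cache)
            e = cache[date]
            is_day = (minutes / 60.0 >= e.civil_dawn) & (
                minutes / 60.0 < e.civil_dusk)
        else:
            theta = minutes * TWO_PI / 1440.0
            is_day = (minutes >= 6 * 60) & (minutes < 18 * 60)
        day_t = temp[d][6:18].mean()
        night_t = np.r_[temp[d][:6], temp[d][18:]].mean()
        tempdiff_z = (day_t - night_t) / 3.0  # approx unit scale
        logit = (truth.base + truth.gain * truth.mixture_density(theta)
                 + truth.moon_slope * moon_daily[d] * (~is_day)
                 + truth.tempdiff_slope * tempdiff_z * is_day)
        p = expit(logit[None, :] + hare_eff[:, None])
        states = rng.random((n_hares, 1440)) < p
        for h in range(n_hares):
            frames.append(pd.DataFrame({
                "hare_id": f"hare{h:03d}",
                "timestamp": base_dt + _dt.timedelta(days=d)
                + pd.to_timedelta(minutes, unit="m"),
                "state": np.where(states[h], "active", "inactive")}))
    activity = pd.concat(frames, ignore_index=True)
    return activity, weather


def gen_nocturnality(coefs: dict[str, float], phi: float, hare_sd: float,
                     n_hares: int, n_days: int, seed: int,
                     sites: tuple[str, ...] = ("wisconsin", "isle_royale",
                                               "yukon")) -> pd.DataFrame:
    """Daily-nocturnality records drawn directly from a beta-GLMM truth.

    ``coefs`` maps design terms to logit-scale values; recognized keys:
    ``(Intercept)``, ``temp_diff``, ``moon``, ``julian``, ``site[<name>]``
    and interactions like ``temp_diff:site[<name>]`` (non-reference sites
    only; the first entry of ``sites`` is the reference). Covariates are
    generated already standardized (temp_diff, julian ~ N(0,1); moon
    uniform on [0,1]).
    """
    rng = np.random.default_rng(seed)
    n = n_hares * n_days
    hare = np.repeat(np.arange(n_hares), n_days)
    site = np.array(sites)[hare % len(sites)]
    temp_diff = rng.standard_normal(n)
    moon = rng.uniform(0, 1, n)
    julian = rng.standard_normal(n)
    eta = np.full(n, coefs.get("(Intercept)", 0.0))
    eta += coefs.get("temp_diff", 0.0) * temp_diff
    eta += coefs.get("moon", 0.0) * moon
    eta += coefs.get("julian", 0.0) * julian
    for s in sites[1:]:
        ind = (site == s).astype(float)
        eta += coefs.get(f"site[{s}]", 0.0) * ind
        eta += coefs.get(f"temp_diff:site[{s}]", 0.0) * temp_diff * ind
        eta += coefs.get(f"moon:site[{s}]", 0.0) * moon * ind
        eta += coefs.get(f"julian:site[{s}]", 0.0) * julian * ind
    eta += rng.normal(0, hare_sd, n_hares)[hare]
    mu = expit(eta)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    return pd.DataFrame({
        "hare_id": [f"hare{h:03d}" for h in hare], "site": site,
        "date": np.tile(np.arange(n_days), n_hares),
        "y": y, "temp_diff": temp_diff, "moon": moon, "julian": julian})


# ---------------------------------------------------------------------------
# SSF tracks

def standardized_buffer_grids(stack: LandscapeStack, radius: float,
                              names=None):
    """Grid-standardized buffered covariate rasters + their scaling.

    Returns ``(grids, scaling)`` where scaling maps name -> (mean, sd) over
    the grid. The truth betas of :class:`SsfTruth` are defined on this
    scale.
    """
    buf = buffered_layers(stack, radius)
    if names is None:
        names = sorted(buf)
    grids, scaling = {}, {}
    for name in names:
        g = buf[name]
        m, s = float(g.mean()), float(g.std())
        s = s if s > 0 else 1.0
        grids[name] = (g - m) / s
        scaling[name] = (m, s)
    return grids, scaling


def gen_tracks(truth: SsfTruth, stack: LandscapeStack, n_hares: int,
               n_steps: int, seed: int, fix_interval_h: float = 4.0,
               n_proposals: int = 50, buffer_radius: float = 50.0,
               hdop_bad_frac: float = 0.05, lowsat_frac: float = 0.02,
               thin_frac: float = 0.0,
               start: _dt.datetime = _dt.datetime(2022, 1, 1, 18, 0),
               winter: int = 2022):
    """Exact finite-proposal SSF simulation over the landscape.

    From each current location, ``n_proposals`` candidate steps are drawn
    from the tentative kernel (gamma lengths, von Mises turns about the
    previous bearing); one is selected with probability proportional to
    ``exp(beta . z(endpoint))`` where z are the grid-standardized 50-m
    buffered covariates. Out-of-extent proposals are reflected back inside.
    HDOP and satellite counts are drawn so a configurable fraction violate
    the retention rules, to exercise filtering.

    Returns ``(fixes, info)``: the GPS fix table and a dict with the truth,
    covariate scaling, and seed.
    """
    rng = np.random.default_rng(seed)
    grids, scaling = standardized_buffer_grids(stack, buffer_radius,
                                               names=sorted(truth.betas))
    beta = np.array([truth.betas[k] for k in sorted(truth.betas)])
    layers = np.stack([grids[k] for k in sorted(truth.betas)])  # (p, nr, nc)
    xmin, xmax, ymin, ymax = stack.extent()
    margin = 2 * stack.cell_size
    lo = np.array([xmin + margin, ymin + margin])
    hi = np.array([xmax - margin, ymax - margin])

    # start positions in the central half of the extent
    pos = np.column_stack([
        rng.uniform(xmin + (xmax - xmin) * 0.3, xmin + (xmax - xmin) * 0.7,
                    n_hares),
        rng.uniform(ymin + (ymax - ymin) * 0.3, ymin + (ymax - ymin) * 0.7,
                    n_hares)])
    bearing = rng.uniform(-np.pi, np.pi, n_hares)

    x0, y0 = stack.origin
    cs = stack.cell_size
    nr, nc = stack.shape

    track_x = np.empty((n_hares, n_steps + 1))
    track_y = np.empty((n_hares, n_steps + 1))
    track_x[:, 0], track_y[:, 0] = pos[:, 0], pos[:, 1]

    for s in range(n_steps):
        sl = rng.gamma(truth.shape, truth.scale, (n_hares, n_proposals))
        if truth.kappa > 0:
            ta = rng.vonmises(0.0, truth.kappa, (n_hares, n_proposals))
        else:
            ta = rng.uniform(-np.pi, np.pi, (n_hares, n_proposals))
        br = bearing[:, None] + ta
        ex = pos[:, 0][:, None] + sl * np.cos(br)
        ey = pos[:, 1][:, None] + sl * np.sin(br)
        # reflect out-of-extent endpoints back inside
        ex = np.where(ex < lo[0], 2 * lo[0] - ex, ex)
        ex = np.where(ex > hi[0], 2 * hi[0] - ex, ex)
        ey = np.where(ey < lo[1], 2 * lo[1] - ey, ey)
        ey = np.where(ey > hi[1], 2 * hi[1] - ey, ey)
        col = np.clip(np.round((ex - x0) / cs).astype(int), 0, nc - 1)
        row = np.clip(np.round((y0 - ey) / cs).astype(int), 0, nr - 1)
        z = layers[:, row, col]  # (p, n_hares, M)
        w = np.exp(np.tensordot(beta, z, axes=1))
        w /= w.sum(axis=1, keepdims=True)
        choice = (w.cumsum(axis=1) > rng.random(n_hares)[:, None]).argmax(axis=1)
        idx = np.arange(n_hares)
        newx, newy = ex[idx, choice], ey[idx, choice]
        bearing = np.arctan2(newy - pos[:, 1], newx - pos[:, 0])
        pos = np.column_stack([newx, newy])
        track_x[:, s + 1], track_y[:, s + 1] = newx, newy

    n_fix = n_steps + 1
    rows = []
    for h in range(n_hares):
        ts = [start + _dt.timedelta(hours=fix_interval_h * i)
              for i in range(n_fix)]
        rows.append(pd.DataFrame({
            "hare_id": f"hare{h:03d}", "winter": winter, "timestamp": ts,
            "x": track_x[h], "y": track_y[h]}))
    fixes = pd.concat(rows, ignore_index=True)
    n = len(fixes)
    hdop = rng.uniform(0.8, 4.8, n)
    bad = rng.random(n) < hdop_bad_frac
    hdop[bad] = rng.uniform(5.05, 9.0, bad.sum())
    nsat = rng.integers(4, 12, n)
    low = rng.random(n) < lowsat_frac
    nsat[low] = rng.integers(0, 3, low.sum())
    fixes["hdop"] = hdop
    fixes["n_sat"] = nsat
    if thin_frac > 0:
        # randomly drop interior fixes to exercise the gap-tolerant resampler
        keep = rng.random(n) >= thin_frac
        keep[::n_fix] = True  # never drop a track's first fix
        fixes = fixes.loc[keep].reset_index(drop=True)
    info = {"truth": truth, "scaling": scaling, "seed": seed,
            "buffer_radius": buffer_radius,
            "covariates": sorted(truth.betas)}
    return fixes, info


# ---------------------------------------------------------------------------
# detections

def gen_detections(truth: OccTruth, stack: LandscapeStack, n_sites: int,
                   n_surveys: int, seed: int, buffer_radius: float = 100.0,
                   winter: int = 2022):
    """Occupancy-governed detection histories on the landscape.

    Camera sites land on random cell centers; occupancy state
    z ~ Bernoulli(psi(site covariates)); detections
    y ~ Bernoulli(z * p(site covariates, survey weather, site intercept)).

    Returns ``(history_df, site_cov, survey_cov, z)`` where history_df is in
    long format (site_id, winter, survey_index, detected).
    """
    if n_surveys < 2:
        raise ValueError("need >= 2 surveys")
    rng = np.random.default_rng(seed)
    grids, scaling = standardized_buffer_grids(stack, buffer_radius)
    nr, nc = stack.shape
    rowi = rng.integers(2, nr - 2, n_sites)
    coli = rng.integers(2, nc - 2, n_sites)
    site_cov = pd.DataFrame({name: g[rowi, coli] for name, g in grids.items()})
    site_cov.insert(0, "site_id", [f"cam{i:03d}" for i in range(n_sites)])
    site_cov["winter"] = winter
    # predator-only detection covariate: distance to a random line network
    from .landscape import distance_to_lines
    xs, ys = stack.cell_centers()
    pts = np.column_stack([xs[coli], ys[rowi]])
    d = distance_to_lines(pts, gen_lines(seed + 3, stack))
    site_cov["dist_linear"] = (d - d.mean()) / (d.std() or 1.0)

    weather = gen_weather(n_surveys * 14, seed + 7)
    temp = weather["temp"].to_numpy().reshape(n_surveys, -1).mean(axis=1)
    snow = weather["snow"].to_numpy().reshape(n_surveys, -1).mean(axis=1)
    survey_cov = pd.DataFrame({
        "survey_index": np.arange(n_surveys),
        "temp": (temp - temp.mean()) / (temp.std() or 1.0),
        "snow": (snow - snow.mean()) / (snow.std() or 1.0)})

    def lp(coefs, row_site, row_survey):
        eta = coefs.get("(Intercept)", 0.0)
        for k, v in coefs.items():
            if k == "(Intercept)":
                continue
            if k in site_cov.columns:
                eta += v * row_site[k]
            elif k in survey_cov.columns:
                eta += v * row_survey[k]
            else:
                raise KeyError(f"unknown covariate {k!r} in truth")
        return eta

    psi = expit(np.array([lp(truth.psi_coefs, site_cov.iloc[i], None)
                          for i in range(n_sites)]))
    z = rng.random(n_sites) < psi
    b = rng.normal(0, truth.site_sd, n_sites)
    recs = []
    for i in range(n_sites):
        for j in range(n_surveys):
            p = expit(lp(truth.p_coefs, site_cov.iloc[i],
                         survey_cov.iloc[j]) + b[i])
            y = int(z[i] and (rng.random() < p))
            recs.append((site_cov["site_id"].iloc[i], winter, j, y))
    history = pd.DataFrame(recs, columns=["site_id", "winter", "survey_index",
                                          "detected"])
    return history, site_cov, survey_cov, z
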