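"""Integrated step selection analysis.

GPS hygiene (HDOP / satellite-count retention), greedy track
regularization to a target fix rate, tentative movement-kernel estimation
(gamma step lengths, von Mises turn angles), random-step generation,
conditional logistic regression over strata of one observed plus m random
steps, the per-individual bootstrap with AICc model choice, and recovery of
the selection-free movement kernel by adding the fitted movement
coefficients to the tentative kernel parameters.

Movement terms (log step length, cosine turn angle) stay on their natural
scale in the design; habitat and environmental covariates are z-scored over
all cases pooled. That convention makes the kernel updates
``k* = k0 + beta_logSL + sum(beta_logSLxE * e)`` and
``kappa* = kappa0 + beta_cosTA + ...`` exact, with environment values e
supplied in SD units (0 = average conditions).
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0, i1
from scipy.stats import gamma as gamma_dist

from .landscape import LandscapeStack, buffered_layers
from .solar_clock import SiteLocation, solar_events

logger = logging.getLogger(__name__)

MOVEMENT_PREFIXES = ("log_sl", "cos_ta")


@dataclass
class MovementKernel:
    """Gamma (shape, scale) x von Mises (kappa) step kernel."""

    shape: float
    scale: float
    kappa: float
    state: str = "tentative"

    def __post_init__(self) -> None:
        if self.state == "tentative" and (self.shape <= 0 or self.scale <= 0):
            raise ValueError("tentative kernel requires shape, scale > 0")
        if self.kappa < 0 and self.state == "tentative":
            raise ValueError("tentative kappa must be >= 0")


@dataclass
class SsfFit:
    """Converged conditional-logistic fit."""

    terms: list[str]
    coefs: np.ndarray
    loglik: float
    aicc: float
    n_strata: int
    cov: np.ndarray | None = None
    scaling: dict = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    converged: bool = True

    def coef(self, term: str) -> float:
        return float(self.coefs[self.terms.index(term)])

    def se(self) -> np.ndarray:
        if self.cov is None:
            return np.full(len(self.coefs), np.nan)
        return np.sqrt(np.diag(self.cov))

    def coefs_raw(self) -> dict[str, float]:
        """Coefficients per raw covariate unit (undo the z-scoring)."""
        out = {}
        for name, b in zip(self.terms, self.coefs):
            s = 1.0
            for part in name.split(":"):
                if part in self.scaling:
                    s *= self.scaling[part][1]
            out[name] = b / s
        return out


@dataclass
class BootstrapSummary:
    mean_weights: dict[str, float]
    top_model: str
    coef_mean: dict[str, float]
    coef_lo: dict[str, float]
    coef_hi: dict[str, float]
    n_boot: int
    replicate_coefs: pd.DataFrame | None = None
    kernels: list[MovementKernel] | None = None


# ---------------------------------------------------------------------------
# GPS hygiene and step construction

def filter_fixes(fixes: pd.DataFrame, max_hdop: float = 5.0,
                 min_sat: int = 3) -> pd.DataFrame:
    """Retain fixes with HDOP <= 5 and >= 3 satellites (boundaries kept)."""
    keep = (fixes["hdop"] <= max_hdop) & (fixes["n_sat"] >= min_sat)
    logger.info("filter_fixes: kept %d of %d fixes", int(keep.sum()), len(fixes))
    return fixes.loc[keep].copy()


def regularize(fixes: pd.DataFrame, target_h: float = 4.0,
               tol_h: float = 2.0) -> pd.DataFrame:
    """Greedy resampling of fixes into steps at target +- tolerance.

    Within each hare x winter track: from the current anchor fix, the step
    endpoint is the earliest later fix whose time gap falls in
    [target - tol, target + tol]; intermediate fixes are skipped. When no
    fix qualifies the anchor advances by one fix and the track fragments
    (turn angles reset across fragments).

    Returns one row per step: start/end coordinates and times, step length
    ``sl``, absolute bearing, turn angle ``ta`` (NaN at fragment starts),
    and derived ``log_sl`` / ``cos_ta``.
    """
    lo = (target_h - tol_h) * 3600.0
    hi = (target_h + tol_h) * 3600.0
    rows = []
    for (hare, winter), g in fixes.groupby(["hare_id", "winter"], sort=True):
        g = g.sort_values("timestamp")
        t = pd.to_datetime(g["timestamp"]).astype("int64").to_numpy() / 1e9
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        i = 0
        fragment = 0
        prev_bearing = np.nan
        while i < len(t) - 1:
            gaps = t[i + 1:] - t[i]
            ok = np.flatnonzero((gaps >= lo) & (gaps <= hi))
            if len(ok) == 0:
                i += 1
                fragment += 1
                prev_bearing = np.nan
                continue
            j = i + 1 + ok[0]
            sl = float(np.hypot(x[j] - x[i], y[j] - y[i]))
            bearing = float(np.arctan2(y[j] - y[i], x[j] - x[i]))
            ta = np.nan
            if np.isfinite(prev_bearing):
                ta = float((bearing - prev_bearing + np.pi) % (2 * np.pi)
                           - np.pi)
            rows.append({
                "hare_id": hare, "winter": winter, "fragment": fragment,
                "t_start": g["timestamp"].iloc[i], "t_end": g["timestamp"].iloc[j],
                "x1": x[i], "y1": y[i], "x2": x[j], "y2": y[j],
                "sl": sl, "bearing": bearing, "ta": ta})
            prev_bearing = bearing
            i = j
    steps = pd.DataFrame(rows)
    if len(steps):
        with np.errstate(divide="ignore"):
            steps["log_sl"] = np.log(steps["sl"])
        steps["cos_ta"] = np.cos(steps["ta"])
    return steps


def assign_diel_phase(steps: pd.DataFrame, site: SiteLocation) -> pd.Series:
    """'night' or 'day' by the civil-twilight phase at each step's start."""
    cache: dict = {}
    out = []
    for ts in pd.to_datetime(steps["t_start"]):
        d = ts.date()
        if d not in cache:
            cache[d] = solar_events(site, d)
        e = cache[d]
        h = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
        out.append("day" if e.civil_dawn <= h < e.civil_dusk else "night")
    return pd.Series(out, index=steps.index)


# ---------------------------------------------------------------------------
# movement kernels

def vonmises_kappa_mle_zero_mean(angles: np.ndarray) -> float:
    """ML kappa of vM(0, kappa): solves A1(kappa) = mean(cos(angle))."""
    c = float(np.mean(np.cos(angles)))
    if c <= 1e-12:
        return 0.0
    c = min(c, 1 - 1e-9)

    def f(k):
        return i1(k) / i0(k) - c

    hi = 2.0
    while f(hi) < 0 and hi < 1e7:
        hi *= 2
    return float(brentq(f, 1e-12, hi, xtol=1e-10))


def fit_tentative(steps: pd.DataFrame, min_sl: int = 20,
                  min_ta: int = 10) -> MovementKernel:
    """Tentative kernel: gamma MLE on step lengths, vM(0, kappa) on turns."""
    sl = steps.loc[steps["sl"] > 0, "sl"].to_numpy(dtype=float)
    ta = steps["ta"].dropna().to_numpy(dtype=float)
    if len(sl) < min_sl:
        raise ValueError(f"need >= {min_sl} positive step lengths, got {len(sl)}")
    if len(ta) < min_ta:
        raise ValueError(f"need >= {min_ta} turn angles, got {len(ta)}")
    if np.ptp(sl) == 0:
        raise ValueError("degenerate (all-equal) step lengths")
    k, _, theta = gamma_dist.fit(sl, floc=0)
    return MovementKernel(shape=float(k), scale=float(theta),
                          kappa=vonmises_kappa_mle_zero_mean(ta))


def sample_random_steps(start_xy, prev_bearing: float, kernel: MovementKernel,
                        m: int = 10, rng=None, seed: int | None = None):
    """m random displacements from the tentative kernel.

    Lengths ~ gamma(k0, theta0); bearings = previous bearing + vM(0, kappa0)
    turns. Returns (x, y, sl, ta) arrays of length m.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sl = rng.gamma(kernel.shape, kernel.scale, m)
    if kernel.kappa > 0:
        ta = rng.vonmises(0.0, kernel.kappa, m)
    else:
        ta = rng.uniform(-np.pi, np.pi, m)
    br = prev_bearing + ta
    x = start_xy[0] + sl * np.cos(br)
    y = start_xy[1] + sl * np.sin(br)
    return x, y, sl, ta


def endpoint_covariates(stack: LandscapeStack, bufgrids: dict,
                        x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Buffered covariates at endpoints by nearest-cell lookup."""
    x0, y0 = stack.origin
    cs = stack.cell_size
    nr, nc = stack.shape
    col = np.clip(np.round((np.asarray(x) - x0) / cs).astype(int), 0, nc - 1)
    row = np.clip(np.round((y0 - np.asarray(y)) / cs).astype(int), 0, nr - 1)
    return pd.DataFrame({name: g[row, col] for name, g in bufgrids.items()})


def _strata_endpoints(obs: pd.DataFrame, kernel: MovementKernel,
                      extent, m: int, rng, max_redraw: int = 100):
    """Vectorized endpoints for N strata: observed first, then m random.

    Returns (x, y, sl, ta) arrays of shape (N, m + 1). Out-of-extent random
    endpoints are redrawn up to ``max_redraw`` rounds; a RuntimeError names
    the strata still out of bounds after that.
    """
    xmin, xmax, ymin, ymax = extent
    n = len(obs)
    prev_bearing = (obs["bearing"] - obs["ta"]).to_numpy(dtype=float)
    x1 = obs["x1"].to_numpy(dtype=float)
    y1 = obs["y1"].to_numpy(dtype=float)
    sl = rng.gamma(kernel.shape, kernel.scale, (n, m))
    if kernel.kappa > 0:
        ta = rng.vonmises(0.0, kernel.kappa, (n, m))
    else:
        ta = rng.uniform(-np.pi, np.pi, (n, m))
    for _ in range(max_redraw):
        br = prev_bearing[:, None] + ta
        ex = x1[:, None] + sl * np.cos(br)
        ey = y1[:, None] + sl * np.sin(br)
        bad = (ex < xmin) | (ex > xmax) | (ey < ymin) | (ey > ymax)
        if not bad.any():
            break
        nb = int(bad.sum())
        sl[bad] = rng.gamma(kernel.shape, kernel.scale, nb)
        if kernel.kappa > 0:
            ta[bad] = rng.vonmises(0.0, kernel.kappa, nb)
        else:
            ta[bad] = rng.uniform(-np.pi, np.pi, nb)
    else:
        raise RuntimeError("random-step proposals persistently out of bounds")
    X = np.column_stack([obs["x2"].to_numpy(dtype=float)[:, None], ex])
    Y = np.column_stack([obs["y2"].to_numpy(dtype=float)[:, None], ey])
    SL = np.column_stack([obs["sl"].to_numpy(dtype=float)[:, None], sl])
    TA = np.column_stack([obs["ta"].to_numpy(dtype=float)[:, None], ta])
    return X, Y, SL, TA


def build_strata(obs_steps: pd.DataFrame, kernel: MovementKernel,
                 stack: LandscapeStack, bufgrids: dict | None = None,
                 m: int = 10, seed: int = 0,
                 buffer_radius: float = 50.0,
                 max_redraw: int = 100) -> pd.DataFrame:
    """Observed + m random steps per stratum, with endpoint covariates.

    Only observed steps with a defined turn angle form strata. Random
    endpoints falling outside the raster extent are redrawn (up to
    ``max_redraw`` rounds).
    """
    rng = np.random.default_rng(seed)
    if bufgrids is None:
        bufgrids = buffered_layers(stack, buffer_radius)
    usable = obs_steps.dropna(subset=["ta"]).reset_index(drop=True)
    X, Y, SL, TA = _strata_endpoints(usable, kernel, stack.extent(), m, rng,
                                     max_redraw)
    n, width = X.shape
    cov = endpoint_covariates(stack, bufgrids, X.ravel(), Y.ravel())
    cov.insert(0, "stratum", np.repeat(np.arange(n), width))
    cov.insert(1, "case", np.tile(np.r_[True, np.zeros(m, dtype=bool)], n))
    cov["sl"] = SL.ravel()
    cov["ta"] = TA.ravel()
    with np.errstate(divide="ignore"):
        cov["log_sl"] = np.log(np.maximum(SL.ravel(), 1e-12))
    cov["cos_ta"] = np.cos(TA.ravel())
    for c in obs_steps.columns:
        if c.startswith("env_"):
            cov[c[4:]] = np.repeat(usable[c].to_numpy(), width)
    return cov


# ---------------------------------------------------------------------------
# conditional logistic regression

def _is_movement(term: str) -> bool:
    return all(p.startswith(MOVEMENT_PREFIXES) for p in term.split(":"))


def _design(cases: pd.DataFrame, terms, standardize: bool = True):
    """Design columns for the listed terms; ':' builds products.

    Habitat/environment components are z-scored over all cases pooled;
    movement components (log_sl, cos_ta) stay raw.
    """
    scaling: dict[str, tuple[float, float]] = {}

    def component(name):
        x = cases[name].to_numpy(dtype=float)
        if standardize and not name.startswith(MOVEMENT_PREFIXES):
            if name not in scaling:
                m, s = float(x.mean()), float(x.std())
                scaling[name] = (m, s if s > 0 else 1.0)
            m, s = scaling[name]
            x = (x - m) / s
        return x

    cols = []
    for t in terms:
        parts = t.split(":")
        x = component(parts[0])
        for p in parts[1:]:
            x = x * component(p)
        cols.append(x)
    return np.column_stack(cols), scaling


def _newton_clogit(Xr: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Newton-Raphson on the stratified conditional likelihood.

    ``Xr`` has shape (n_strata, n_alt, p) with the observed alternative
    first. Returns (beta, loglik, cov, converged).
    """
    n_strata, _, p = Xr.shape
    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False

    def loglik_parts(b):
        eta = Xr @ b
        mx = eta.max(axis=1, keepdims=True)
        w = np.exp(eta - mx)
        denom = w.sum(axis=1, keepdims=True)
        ll = float((eta[:, 0] - (mx[:, 0] + np.log(denom[:, 0]))).sum())
        return ll, w / denom

    for _ in range(max_iter):
        ll, w = loglik_parts(beta)
        xbar = np.einsum("sa,sap->sp", w, Xr)
        grad = (Xr[:, 0, :] - xbar).sum(axis=0)
        hess = -(np.einsum("sa,sap,saq->pq", w, Xr, Xr)
                 - np.einsum("sp,sq->pq", xbar, xbar))
        if np.linalg.norm(grad) < tol and ll <= ll_prev + 1e-12:
            converged = True
            break
        try:
            step = np.linalg.solve(hess - 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        t_ = 1.0
        for _h in range(30):  # step-halving safeguard
            if loglik_parts(beta - t_ * step)[0] >= ll - 1e-12:
                break
            t_ *= 0.5
        beta = beta - t_ * step
        ll_prev = ll
        if np.linalg.norm(beta) > 50:
            warnings.warn("coefficient norm > 50: possible separation")
            break
    ll, w = loglik_parts(beta)
    xbar = np.einsum("sa,sap->sp", w, Xr)
    hess = -(np.einsum("sa,sap,saq->pq", w, Xr, Xr)
             - np.einsum("sp,sq->pq", xbar, xbar))
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = None
    return beta, ll, cov, converged


def fit_clogit(cases: pd.DataFrame, terms, standardize: bool = True,
               max_iter: int = 50, tol: float = 1e-8) -> SsfFit:
    """Conditional logistic regression with step strata.

    Maximizes sum over strata of [x_obs . beta - log sum_alt exp(x_alt . beta)]
    by Newton-Raphson with analytic gradient and Hessian. Covariates that
    are constant within every stratum carry no information and are dropped
    with a warning; a diverging norm (>50 after standardization) flags the
    fit as non-converged (complete separation).
    """
    df = cases.sort_values(["stratum", "case"], ascending=[True, False])
    strata, counts = np.unique(df["stratum"].to_numpy(), return_counts=True)
    if len(set(counts)) != 1:
        raise ValueError("strata differ in size; expected 1 observed + m random")
    n_alt = int(counts[0])
    n_strata = len(strata)
    if not df.groupby("stratum", sort=True)["case"].first().all():
        raise ValueError("each stratum needs exactly one observed case")
    X, scaling = _design(df, list(terms), standardize)
    Xr = X.reshape(n_strata, n_alt, -1)

    keep, dropped = [], []
    for j, t in enumerate(terms):
        if Xr[:, :, j].var(axis=1).max() < 1e-12:
            dropped.append(t)
        else:
            keep.append(j)
    if dropped:
        warnings.warn(f"dropping stratum-constant terms: {dropped}")
    terms_kept = [t for t in terms if t not in dropped]
    Xr = Xr[:, :, keep]
    beta, ll, cov, converged = _newton_clogit(Xr, max_iter, tol)
    k = len(terms_kept)
    n = n_strata
    a = (-2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
         if n > k + 1 else np.inf)
    return SsfFit(terms=terms_kept, coefs=beta, loglik=ll, aicc=a,
                  n_strata=n_strata, cov=cov, scaling=scaling,
                  dropped=dropped, converged=converged)


def candidate_models_ssf(base_terms, interaction_pool) -> list[list[str]]:
    """Base model plus all one- and two-interaction extensions."""
    from itertools import combinations

    base = list(base_terms)
    out = [base]
    pool = list(dict.fromkeys(interaction_pool))
    for i in pool:
        out.append(base + [i])
    for i, j in combinations(pool, 2):
        out.append(base + [i, j])
    # dedupe on term sets
    seen, uniq = set(), []
    for c in out:
        key = frozenset(c)
        if key not in seen:
            seen.add(key)
            uniq.append(c)
    return uniq


def selection_free_kernel(fit: SsfFit, tentative: MovementKernel,
                          env: dict[str, float] | None = None) -> MovementKernel:
    """Update the tentative kernel with the fitted movement coefficients.

    k* = k0 + beta_logSL + sum_e beta_(logSL:e) * e (gamma scale unchanged);
    kappa* = kappa0 + beta_cosTA + sum_e beta_(cosTA:e) * e, with env values
    in SD units (default all 0 = average conditions).
    """
    env = env or {}
    k_star = tentative.shape
    kappa_star = tentative.kappa
    for t, b in zip(fit.terms, fit.coefs):
        parts = t.split(":")
        if parts[0] == "log_sl":
            mult = 1.0
            for pzt in parts[1:]:
                mult *= env.get(pzt, 0.0)
            k_star += b * mult
        elif parts[0] == "cos_ta":
            mult = 1.0
            for pzt in parts[1:]:
                mult *= env.get(pzt, 0.0)
            kappa_star += b * mult
    if k_star <= 0:
        raise ValueError(f"invalid selection-free shape {k_star:.3f} at env {env}")
    if kappa_star < 0:
        warnings.warn("negative selection-free kappa: reversed-mode turning")
    return MovementKernel(shape=float(k_star), scale=tentative.scale,
                          kappa=float(kappa_star), state="selection-free")


# ---------------------------------------------------------------------------
# per-individual bootstrap

def aicc_weights(aiccs: np.ndarray) -> np.ndarray:
    d = aiccs - np.nanmin(aiccs)
    w = np.exp(-0.5 * d)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


def bootstrap_ssf(obs_steps: pd.DataFrame, stack: LandscapeStack,
                  candidates: list[list[str]], n_boot: int = 1000,
                  n_obs: int = 25, m: int = 10, seed: int = 20180101,
                  buffer_radius: float = 50.0, kernels: dict | None = None,
                  take_all: bool = False) -> BootstrapSummary:
    """Per-individual bootstrap over hare x winter units.

    Units with fewer than ``n_obs`` observed steps are excluded (logged).
    Each replicate resamples ``n_obs`` observed steps with replacement per
    unit, regenerates ``m`` random steps per observed step from the unit's
    tentative kernel, standardizes covariates within the replicate, and fits
    every candidate. The top model has the largest mean AICc weight;
    coefficient means and percentile 95% CIs come from its replicates.
    With ``take_all=True`` (debug) the full observed set is used unchanged.
    """
    rng = np.random.default_rng(seed)
    bufgrids = buffered_layers(stack, buffer_radius)
    extent = stack.extent()
    units = []
    for (hare, winter), g in obs_steps.groupby(["hare_id", "winter"]):
        g = g.dropna(subset=["ta"])
        if len(g) < n_obs and not take_all:
            logger.info("excluding %s/%s: %d < %d observed steps",
                        hare, winter, len(g), n_obs)
            continue
        units.append(((hare, winter), g.reset_index(drop=True)))
    if not units:
        raise ValueError("no hare x winter units meet the step threshold")
    if kernels is None:
        kernels = {key: fit_tentative(g) for key, g in units}

    all_terms = sorted({t for c in candidates for t in c})
    components = sorted({p for t in all_terms for p in t.split(":")})
    env_cols = [c for c in obs_steps.columns if c.startswith("env_")]

    names = ["m%d" % i for i in range(len(candidates))]
    weights = np.zeros((n_boot, len(candidates)))
    coef_rows: list[dict] = [dict() for _ in range(n_boot)]
    failures = 0
    for r in range(n_boot):
        xs, ys, sls, tas, envs = [], [], [], [], []
        for key, g in units:
            sample = g if take_all else g.iloc[rng.integers(0, len(g), n_obs)]
            X, Y, SL, TA = _strata_endpoints(sample, kernels[key], extent,
                                             m, rng)
            xs.append(X); ys.append(Y); sls.append(SL); tas.append(TA)
            if env_cols:
                envs.append(sample[env_cols].to_numpy(dtype=float))
        X = np.vstack(xs); Y = np.vstack(ys)
        SL = np.vstack(sls); TA = np.vstack(tas)
        n, width = X.shape
        cov = endpoint_covariates(stack, bufgrids, X.ravel(), Y.ravel())
        arrs = {name: cov[name].to_numpy().reshape(n, width)
                for name in cov.columns}
        with np.errstate(divide="ignore"):
            arrs["log_sl"] = np.log(np.maximum(SL, 1e-12))
        arrs["cos_ta"] = np.cos(TA)
        if env_cols:
            env = np.vstack(envs)
            for j, c in enumerate(env_cols):
                arrs[c[4:]] = np.repeat(env[:, j:j + 1], width, axis=1)
        # standardize habitat/env components over all cases pooled
        scaling = {}
        std = {}
        for cname in components:
            a = arrs[cname]
            if cname.startswith(MOVEMENT_PREFIXES):
                std[cname] = a
            else:
                mu, sd = float(a.mean()), float(a.std())
                sd = sd if sd > 0 else 1.0
                scaling[cname] = (mu, sd)
                std[cname] = (a - mu) / sd
        design = {}
        for t in all_terms:
            parts_ = t.split(":")
            x = std[parts_[0]]
            for pzt in parts_[1:]:
                x = x * std[pzt]
            design[t] = x
        fits = []
        ok = True
        for cand in candidates:
            Xr = np.stack([design[t] for t in cand], axis=2)
            try:
                beta, ll, covm, conv = _newton_clogit(Xr)
                if not conv:
                    raise RuntimeError("clogit did not converge")
                k = len(cand)
                a_ = (-2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
                      if n > k + 1 else np.inf)
                fits.append((cand, beta, a_))
            except Exception:  # noqa: BLE001 - replicate-level failure
                ok = False
                break
        if not ok:
            failures += 1
            weights[r] = np.nan
            continue
        weights[r] = aicc_weights(np.array([f[2] for f in fits]))
        best = int(np.argmax(weights[r]))
        cand, beta, _ = fits[best]
        raw = {}
        for t, b in zip(cand, beta):
            s = 1.0
            for pzt in t.split(":"):
                if pzt in scaling:
                    s *= scaling[pzt][1]
            raw[t] = b / s  # natural covariate scale: comparable across reps
        coef_rows[r] = {"model": names[best], **raw}
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap replicates failed")
    mean_w = np.nanmean(weights, axis=0)
    top = int(np.argmax(mean_w))
    reps = pd.DataFrame([cr for cr in coef_rows if cr.get("model") == names[top]])
    coef_mean, lo, hi = {}, {}, {}
    for t in all_terms:
        if t in reps.columns:
            v = reps[t].dropna().to_numpy(dtype=float)
            if len(v):
                coef_mean[t] = float(v.mean())
                lo[t], hi[t] = (float(x) for x in np.percentile(v, [2.5, 97.5]))
    return BootstrapSummary(
        mean_weights=dict(zip(names, mean_w)), top_model=names[top],
        coef_mean=coef_mean, coef_lo=lo, coef_hi=hi, n_boot=n_boot,
        replicate_coefs=reps)
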