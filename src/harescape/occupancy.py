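"""Single-season single-species occupancy models for camera data.

Separates probability of occurrence (psi) from per-survey detection
probability (p) using repeated two-week detection/nondetection surveys.
Detection can carry a site random intercept (marginalized by Gauss-Hermite
quadrature); goodness of fit is assessed by the MacKenzie-Bailey chi-square
with a parametric-bootstrap null, and the resulting overdispersion ratio
c-hat inflates standard errors when above 1.

Interpretation note: with cameras sampling use rather than closure, p is
read as the intensity of species activity at a site; nothing in the
computation depends on that reading.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, roots_hermite

logger = logging.getLogger(__name__)


@dataclass
class DetectionHistory:
    """Site x survey 0/1/NaN matrix with covariates.

    ``site_cov`` has one row per site (camera x winter unit); ``survey_cov``
    one row per survey with covariates shared across sites (mean temperature
    and snow depth over the window).
    """

    y: np.ndarray
    site_cov: pd.DataFrame
    survey_cov: pd.DataFrame

    def __post_init__(self) -> None:
        if self.y.shape[1] < 2:
            raise ValueError("need >= 2 surveys")
        if self.y.shape[0] != len(self.site_cov):
            raise ValueError("site covariate rows != history rows")


@dataclass
class OccupancyFit:
    psi_terms: list[str]
    p_terms: list[str]
    psi_coefs: np.ndarray
    p_coefs: np.ndarray
    psi_names: list[str]
    p_names: list[str]
    sigma_site: float
    loglik: float
    aicc: float
    n_sites: int
    k: int
    cov: np.ndarray | None = None
    scaling: dict = field(default_factory=dict)
    c_hat: float | None = None
    gof_p: float | None = None
    converged: bool = True

    def se(self) -> np.ndarray:
        """Raw SEs for (psi coefs, p coefs) in order."""
        if self.cov is None:
            return np.full(len(self.psi_coefs) + len(self.p_coefs), np.nan)
        return np.sqrt(np.diag(self.cov)[: len(self.psi_coefs)
                                         + len(self.p_coefs)])

    def se_corrected(self) -> np.ndarray:
        infl = np.sqrt(max(self.c_hat, 1.0)) if self.c_hat is not None else 1.0
        return self.se() * infl


def pool_species(detections: pd.DataFrame,
                 species_map: dict[str, str]) -> pd.DataFrame:
    """Collapse species into guild groups (e.g. coyote/fox -> canid)."""
    out = detections.copy()
    out["species"] = out["species"].map(lambda s: species_map.get(s, s))
    return out


def build_history(detections: pd.DataFrame, deployments: pd.DataFrame,
                  window_days: int = 14, min_trailing_days: int = 7,
                  weather: pd.DataFrame | None = None,
                  site_cov: pd.DataFrame | None = None,
                  season_end: tuple[int, int] = (4, 30)) -> DetectionHistory:
    """Assemble a 2-week-format detection history.

    Surveys are consecutive ``window_days`` windows anchored at Jan 1 of
    each winter and capped at ``season_end`` (month, day); a trailing
    partial window shorter than ``min_trailing_days`` is dropped. A cell is
    1 when >= 1 detection falls in the window, 0 when the camera was active
    but silent, NaN when inactive (no deployment overlap). Survey
    covariates are the mean daily temperature and snow depth over each
    window when ``weather`` is given.
    """
    deps = deployments.copy()
    deps["start"] = pd.to_datetime(deps["start"])
    deps["end"] = pd.to_datetime(deps["end"])
    for (site, winter), g in deps.groupby(["site_id", "winter"]):
        g = g.sort_values("start")
        if (g["start"].iloc[1:].to_numpy()
                < g["end"].iloc[:-1].to_numpy()).any():
            raise ValueError(f"overlapping deployments at {site}/{winter}")
    det = detections.copy()
    det["timestamp"] = pd.to_datetime(det["timestamp"])
    units = deps[["site_id", "winter"]].drop_duplicates().reset_index(drop=True)
    winters = sorted(units["winter"].unique())
    spans = {}
    for w in winters:
        start = _dt.datetime(int(w), 1, 1)
        end = min(deps.loc[deps["winter"] == w, "end"].max(),
                  pd.Timestamp(_dt.datetime(int(w), *season_end)))
        n_full = int(((end - start).days) // window_days)
        rem = (end - start).days - n_full * window_days
        n = n_full + (1 if rem >= min_trailing_days else 0)
        spans[w] = (start, n)
    n_surveys = max(n for _, n in spans.values())
    y = np.full((len(units), n_surveys), np.nan)
    for i, (site, winter) in units.iterrows():
        start, n = spans[winter]
        dep = deps[(deps["site_id"] == site) & (deps["winter"] == winter)]
        d = det[(det["site_id"] == site) & (det["winter"] == winter)]
        for j in range(n):
            w0 = start + _dt.timedelta(days=window_days * j)
            w1 = w0 + _dt.timedelta(days=window_days)
            active = ((dep["start"] < w1) & (dep["end"] > w0)).any()
            if not active:
                continue
            hit = ((d["timestamp"] >= w0) & (d["timestamp"] < w1)).any()
            y[i, j] = 1.0 if hit else 0.0
        if np.isnan(y[i]).all():
            logger.info("camera %s/%s inactive all winter", site, winter)
    srows = []
    for j in range(n_surveys):
        row = {"survey_index": j}
        if weather is not None:
            wts = pd.to_datetime(weather["timestamp"])
            mask = np.zeros(len(weather), dtype=bool)
            for w in winters:
                start, n = spans[w]
                if j < n:
                    w0 = start + _dt.timedelta(days=window_days * j)
                    w1 = w0 + _dt.timedelta(days=window_days)
                    mask |= ((wts >= w0) & (wts < w1)).to_numpy()
            row["temp"] = float(weather.loc[mask, "temp"].mean()) if mask.any() else np.nan
            row["snow"] = float(weather.loc[mask, "snow"].mean()) if mask.any() else np.nan
        srows.append(row)
    if site_cov is None:
        site_cov = units.copy()
    else:
        site_cov = units.merge(site_cov, on=["site_id", "winter"], how="left")
    return DetectionHistory(y=y, site_cov=site_cov.reset_index(drop=True),
                            survey_cov=pd.DataFrame(srows))


def history_from_long(history: pd.DataFrame, site_cov: pd.DataFrame,
                      survey_cov: pd.DataFrame) -> DetectionHistory:
    """DetectionHistory from a long (site_id, winter, survey_index, detected)
    table such as the synthetic generator emits."""
    wide = history.pivot_table(index=["site_id", "winter"],
                               columns="survey_index", values="detected")
    sc = site_cov.set_index(["site_id", "winter"]).loc[wide.index].reset_index()
    return DetectionHistory(y=wide.to_numpy(dtype=float), site_cov=sc,
                            survey_cov=survey_cov)


def psi_candidates(landscape_terms) -> list[list[str]]:
    """The three occupancy structures: constant; year; year + landscape."""
    return [[], ["year"], ["year"] + list(landscape_terms)]


def _build_design(df: pd.DataFrame, terms, scaling, standardize):
    cols, names = [np.ones(len(df))], ["(Intercept)"]
    for t in terms:
        if t == "year":
            levels = sorted(df["winter"].unique())
            for lv in levels[1:]:
                cols.append((df["winter"] == lv).to_numpy(dtype=float))
                names.append(f"year[{lv}]")
            continue
        x = df[t].to_numpy(dtype=float)
        if standardize:
            if t not in scaling:
                m, s = float(np.nanmean(x)), float(np.nanstd(x))
                scaling[t] = (m, s if s > 0 else 1.0)
            m, s = scaling[t]
            x = (x - m) / s
        cols.append(x)
        names.append(t)
    return np.column_stack(cols), names


def _p_design(history: DetectionHistory, p_terms, scaling, standardize):
    """(sites, p, surveys) detection design: site terms broadcast over
    surveys, survey terms over sites."""
    y = history.y
    n_sites, n_surveys = y.shape
    site_cols, p_names = _build_design(history.site_cov, [
        t for t in p_terms if t == "year" or t in history.site_cov.columns],
        scaling, standardize)
    survey_terms = [t for t in p_terms if t != "year"
                    and t not in history.site_cov.columns]
    Xp_parts = [np.repeat(site_cols[:, :, None], n_surveys, axis=2)]
    for t in survey_terms:
        x = history.survey_cov[t].to_numpy(dtype=float)
        if standardize:
            if t not in scaling:
                m, s = float(np.nanmean(x)), float(np.nanstd(x))
                scaling[t] = (m, s if s > 0 else 1.0)
        m, s = scaling.get(t, (0.0, 1.0))
        x = (x - m) / s
        Xp_parts.append(np.broadcast_to(x[None, None, :],
                                        (n_sites, 1, n_surveys)).copy())
        p_names = p_names + [t]
    return np.concatenate(Xp_parts, axis=1), p_names


def make_negloglik(history: DetectionHistory, psi_terms=(), p_terms=(),
                   random_intercept: bool = True, n_quad: int = 15,
                   standardize: bool = True):
    """Marginal negative log-likelihood of the occupancy model.

    Returns ``(negloglik, meta)`` where negloglik takes the parameter
    vector (psi coefs, p coefs[, log sigma]) and meta carries design names
    and covariate scaling.
    """
    y = history.y
    scaling: dict = {}
    Xpsi, psi_names = _build_design(history.site_cov, psi_terms, scaling,
                                    standardize)
    Xp, p_names = _p_design(history, p_terms, scaling, standardize)
    pa, pp = Xpsi.shape[1], Xp.shape[1]
    obs = ~np.isnan(y)
    y0 = np.nan_to_num(y)
    never = (y0.sum(axis=1) == 0)
    nodes, wts = roots_hermite(n_quad)
    logw = np.log(wts) - 0.5 * np.log(np.pi)

    def negloglik(theta):
        a = theta[:pa]
        g = theta[pa:pa + pp]
        sigma = np.exp(theta[-1]) if random_intercept else 0.0
        psi = expit(Xpsi @ a)
        eta = np.einsum("spj,p->sj", Xp, g)
        if random_intercept:
            etab = eta[None, :, :] + np.sqrt(2.0) * sigma * nodes[:, None, None]
        else:
            etab = eta[None, :, :]
        ll_det = np.where(obs[None, :, :],
                          y0[None, :, :] * (-np.logaddexp(0, -etab))
                          + (1 - y0[None, :, :]) * (-np.logaddexp(0, etab)),
                          0.0).sum(axis=2)  # (K, sites)
        if random_intercept:
            cond = logsumexp(logw[:, None] + ll_det, axis=0)
        else:
            cond = ll_det[0]
        with np.errstate(divide="ignore"):
            log_occ = np.log(psi) + cond
            contrib = np.where(
                never,
                np.logaddexp(log_occ, np.log1p(-psi)),
                log_occ)
        return -contrib.sum()

    meta = {"pa": pa, "pp": pp, "psi_names": psi_names, "p_names": p_names,
            "scaling": scaling}
    return negloglik, meta


def fit_occupancy(history: DetectionHistory, psi_terms=(), p_terms=(),
                  random_intercept: bool = True, n_quad: int = 15,
                  standardize: bool = True, start=None) -> OccupancyFit:
    """MLE of the single-season occupancy model.

    Per-site marginal likelihood
    ``psi_i * E_b[ prod_j p_ij(b)^y (1 - p_ij(b))^(1-y) ] + (1 - psi_i) *
    I[all y_ij = 0]`` with the site intercept b inside p's logit integrated
    by Gauss-Hermite quadrature; NaN surveys are skipped. Quasi-Newton
    optimization; SEs from the numeric Hessian.
    """
    n_sites = history.y.shape[0]
    negloglik, meta = make_negloglik(history, psi_terms, p_terms,
                                     random_intercept, n_quad, standardize)
    pa, pp = meta["pa"], meta["pp"]
    psi_names, p_names = meta["psi_names"], meta["p_names"]
    scaling = meta["scaling"]

    if start is None:
        start = np.zeros(pa + pp + (1 if random_intercept else 0))
        start[pa] = -1.0
        if random_intercept:
            start[-1] = np.log(0.3)
    res = minimize(negloglik, start, method="L-BFGS-B",
                   options={"maxiter": 1000})
    theta = res.x
    npar = pa + pp + (1 if random_intercept else 0)
    # numeric Hessian (central differences)
    Hm = np.zeros((npar, npar))
    h = 1e-4
    for i_ in range(npar):
        for j_ in range(i_, npar):
            ei = np.zeros(npar); ei[i_] = h
            ej = np.zeros(npar); ej[j_] = h
            f = negloglik
            Hm[i_, j_] = Hm[j_, i_] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)) / (4 * h * h)
    try:
        cov = np.linalg.inv(Hm)
    except np.linalg.LinAlgError:
        cov = None
    loglik = -res.fun
    k = npar
    n = n_sites
    a_ = (-2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
          if n > k + 1 else np.inf)
    return OccupancyFit(
        psi_terms=list(psi_terms), p_terms=list(p_terms),
        psi_coefs=theta[:pa], p_coefs=theta[pa:pa + pp],
        psi_names=psi_names, p_names=p_names,
        sigma_site=float(np.exp(theta[-1])) if random_intercept else 0.0,
        loglik=loglik, aicc=a_, n_sites=n_sites, k=k, cov=cov,
        scaling=scaling, converged=bool(res.success))


def _pattern_chi2(fit: OccupancyFit, history: DetectionHistory,
                  n_quad: int = 15) -> float:
    """MacKenzie-Bailey chi-square, cohorted by missingness pattern."""
    y = history.y
    n_sites, n_surveys = y.shape
    scaling = dict(fit.scaling)
    Xpsi, _ = _build_design(history.site_cov, fit.psi_terms, scaling, True)
    psi = expit(Xpsi @ fit.psi_coefs)
    site_cols, _ = _build_design(history.site_cov, [
        t for t in fit.p_terms if t == "year" or t in history.site_cov.columns],
        scaling, True)
    parts = [np.repeat(site_cols[:, :, None], n_surveys, axis=2)]
    for t in [t for t in fit.p_terms if t != "year"
              and t not in history.site_cov.columns]:
        x = history.survey_cov[t].to_numpy(dtype=float)
        m, s = scaling.get(t, (0.0, 1.0))
        parts.append(np.broadcast_to(((x - m) / s)[None, None, :],
                                     (n_sites, 1, n_surveys)))
    Xp = np.concatenate(parts, axis=1)
    eta = np.einsum("spj,p->sj", Xp, fit.p_coefs)
    nodes, wts = roots_hermite(n_quad)
    logw = np.log(wts) - 0.5 * np.log(np.pi)
    sigma = fit.sigma_site
    chi2 = 0.0
    masks = pd.DataFrame(~np.isnan(y))
    for mask_key, grp in masks.groupby(list(masks.columns)):
        idx = grp.index.to_numpy()
        cols = np.flatnonzero(np.array(mask_key))
        if len(cols) == 0:
            continue
        sub_y = y[np.ix_(idx, cols)]
        sub_eta = eta[np.ix_(idx, cols)]
        npat = 2 ** len(cols)
        pats = ((np.arange(npat)[:, None] >> np.arange(len(cols))) & 1
                ).astype(float)  # (npat, J)
        etab = sub_eta[None, :, :] + np.sqrt(2) * sigma * nodes[:, None, None]
        logp = -np.logaddexp(0, -etab)
        log1mp = -np.logaddexp(0, etab)
        # (K, sites, npat)
        ll = np.einsum("ksj,pj->ksp", logp, pats) + np.einsum(
            "ksj,pj->ksp", log1mp, 1 - pats)
        cond = logsumexp(logw[:, None, None] + ll, axis=0)  # (sites, npat)
        P = psi[idx][:, None] * np.exp(cond)
        allzero = pats.sum(axis=1) == 0
        P[:, allzero] += (1 - psi[idx])[:, None]
        E = P.sum(axis=0)
        codes = (sub_y * (2 ** np.arange(len(cols)))[None, :]).sum(axis=1)
        O = np.bincount(codes.astype(int), minlength=npat)
        with np.errstate(divide="ignore", invalid="ignore"):
            cell = (O - E) ** 2 / E
        chi2 += float(np.nansum(np.where(E > 0, cell, 0.0)))
    return chi2


def _simulate_from_fit(fit: OccupancyFit, history: DetectionHistory,
                       rng) -> DetectionHistory:
    y = history.y
    n_sites, n_surveys = y.shape
    scaling = dict(fit.scaling)
    Xpsi, _ = _build_design(history.site_cov, fit.psi_terms, scaling, True)
    psi = expit(Xpsi @ fit.psi_coefs)
    site_cols, _ = _build_design(history.site_cov, [
        t for t in fit.p_terms if t == "year" or t in history.site_cov.columns],
        scaling, True)
    parts = [np.repeat(site_cols[:, :, None], n_surveys, axis=2)]
    for t in [t for t in fit.p_terms if t != "year"
              and t not in history.site_cov.columns]:
        x = history.survey_cov[t].to_numpy(dtype=float)
        m, s = scaling.get(t, (0.0, 1.0))
        parts.append(np.broadcast_to(((x - m) / s)[None, None, :],
                                     (n_sites, 1, n_surveys)))
    Xp = np.concatenate(parts, axis=1)
    eta = np.einsum("spj,p->sj", Xp, fit.p_coefs)
    b = rng.normal(0, fit.sigma_site, n_sites)
    p = expit(eta + b[:, None])
    z = rng.random(n_sites) < psi
    ysim = (rng.random((n_sites, n_surveys)) < p) & z[:, None]
    ysim = ysim.astype(float)
    ysim[np.isnan(y)] = np.nan
    return DetectionHistory(y=ysim, site_cov=history.site_cov,
                            survey_cov=history.survey_cov)


def mackenzie_bailey(fit: OccupancyFit, history: DetectionHistory,
                     n_boot: int = 1000, seed: int = 0) -> OccupancyFit:
    """Parametric-bootstrap goodness of fit; attaches c_hat and a p-value.

    Observed chi-square over detection-history patterns is compared with its
    null distribution from data simulated (and refitted) under the fitted
    model; c_hat = observed / mean(bootstrap).
    """
    rng = np.random.default_rng(seed)
    obs = _pattern_chi2(fit, history)
    start = np.concatenate([fit.psi_coefs, fit.p_coefs,
                            [np.log(max(fit.sigma_site, 1e-3))]])
    vals = []
    failures = 0
    for _ in range(n_boot):
        sim = _simulate_from_fit(fit, history, rng)
        try:
            refit = fit_occupancy(sim, fit.psi_terms, fit.p_terms,
                                  start=start)
            vals.append(_pattern_chi2(refit, sim))
        except Exception:  # noqa: BLE001
            failures += 1
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    vals = np.asarray(vals)
    c_hat = float(obs / vals.mean())
    p = float(np.mean(vals >= obs))
    return replace(fit, c_hat=c_hat, gof_p=p)


def correct_se(fit: OccupancyFit) -> OccupancyFit:
    """Inflate SEs by sqrt(c_hat) when c_hat > 1 (no-op otherwise)."""
    if fit.c_hat is None:
        raise ValueError("run mackenzie_bailey first")
    return fit  # se_corrected() applies the inflation lazily


def wald_cis(fit: OccupancyFit, corrected: bool = True) -> pd.DataFrame:
    se = fit.se_corrected() if corrected else fit.se()
    names = [f"psi:{n}" for n in fit.psi_names] + [f"p:{n}" for n in fit.p_names]
    est = np.concatenate([fit.psi_coefs, fit.p_coefs])
    return pd.DataFrame({"term": names, "estimate": est, "se": se,
                         "lo": est - 1.96 * se, "hi": est + 1.96 * se})
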