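"""Detection histories, occupancy likelihood, GOF, and SE correction."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brute
from scipy.special import expit

from harescape import occupancy as occ
from harescape import synthetic_data as syn


def _toy_history():
    y = np.array([[1, 0, 1, 0], [0, 0, 0, 0], [1, 1, 0, 1],
                  [0, 1, 0, 0], [0, 0, 0, 0], [1, 0, 0, 0]], dtype=float)
    site_cov = pd.DataFrame({"site_id": [f"s{i}" for i in range(6)],
                             "winter": 2022})
    survey_cov = pd.DataFrame({"survey_index": range(4)})
    return occ.DetectionHistory(y=y, site_cov=site_cov, survey_cov=survey_cov)


class TestBuildHistory:
    def _inputs(self):
        deployments = pd.DataFrame({
            "site_id": ["c1", "c2"], "winter": [2022, 2022],
            "start": ["2022-01-01", "2022-01-15"],
            "end": ["2022-02-26", "2022-02-26"]})
        detections = pd.DataFrame({
            "site_id": ["c1", "c1", "c1", "c2"], "winter": 2022,
            "timestamp": ["2022-01-02", "2022-01-05", "2022-01-09",
                          "2022-02-20"]})
        return detections, deployments

    def test_hand_assembled_matrix(self):
        """2 cameras, 8 weeks -> 2x4 matrix asserted cellwise."""
        detections, deployments = self._inputs()
        h = occ.build_history(detections, deployments)
        want = np.array([[1, 0, 0, 0],
                         [np.nan, 0, 0, 1]])
        np.testing.assert_array_equal(h.y, want)

    def test_multiple_detections_one_window_single_one(self):
        detections, deployments = self._inputs()
        h = occ.build_history(detections, deployments)
        assert h.y[0, 0] == 1.0  # 3 detections in window 1 -> one 1

    def test_inactive_camera_all_nan(self):
        deployments = pd.DataFrame({
            "site_id": ["c1", "c2"], "winter": 2022,
            "start": ["2022-01-01", "2022-06-01"],
            "end": ["2022-02-26", "2022-06-02"]})
        detections = pd.DataFrame({"site_id": ["c1"], "winter": 2022,
                                   "timestamp": ["2022-01-02"]})
        h = occ.build_history(detections, deployments)
        assert np.isnan(h.y[1]).all()

    def test_overlapping_deployments_rejected(self):
        deployments = pd.DataFrame({
            "site_id": ["c1", "c1"], "winter": 2022,
            "start": ["2022-01-01", "2022-01-20"],
            "end": ["2022-02-01", "2022-02-26"]})
        with pytest.raises(ValueError, match="overlap"):
            occ.build_history(pd.DataFrame({"site_id": [], "winter": [],
                                            "timestamp": []}), deployments)

    def test_survey_weather_means(self):
        detections, deployments = self._inputs()
        weather = syn.gen_weather(56, 3)
        h = occ.build_history(detections, deployments, weather=weather)
        w0 = weather[pd.to_datetime(weather["timestamp"])
                     < dt.datetime(2022, 1, 15)]
        assert h.survey_cov["temp"].iloc[0] == pytest.approx(
            w0["temp"].mean())


class TestPoolSpecies:
    def test_wisconsin_guild_mapping(self):
        df = pd.DataFrame({"species": ["coyote", "red_fox", "fisher",
                                       "ermine", "lynx"]})
        mapping = {"coyote": "canid", "red_fox": "canid",
                   "fisher": "mustelid", "ermine": "mustelid"}
        out = occ.pool_species(df, mapping)
        assert list(out["species"]) == ["canid", "canid", "mustelid",
                                        "mustelid", "lynx"]


class TestFitOccupancy:
    def test_forced_perfect_detection_gives_naive_occupancy(self):
        h = _toy_history()
        # fix p ~ 1 by a huge offset: constant-p model fitted freely would
        # not reach 1, so check the limit algebraically via the psi MLE
        fit = occ.fit_occupancy(h, [], [], random_intercept=False)
        naive = 4 / 6
        psi_hat = expit(fit.psi_coefs[0])
        assert psi_hat >= naive - 1e-6

    def test_matches_grid_search_oracle(self):
        h = _toy_history()
        fit = occ.fit_occupancy(h, [], [], random_intercept=False)

        y = h.y

        def nll(params):
            a, g = params
            psi, p = expit(a), expit(g)
            L = 0.0
            for i in range(len(y)):
                det = np.prod(p ** y[i] * (1 - p) ** (1 - y[i]))
                L += np.log(psi * det + (1 - psi) * (y[i].sum() == 0))
            return -L

        best = brute(nll, [(-3, 3), (-3, 3)], Ns=301, full_output=True)
        assert fit.psi_coefs[0] == pytest.approx(best[0][0], abs=1e-3)
        assert fit.p_coefs[0] == pytest.approx(best[0][1], abs=1e-3)
        assert -fit.loglik == pytest.approx(best[1], abs=1e-4)

    def test_sigma_zero_limit_matches_closed_form(self):
        """The GH-marginalized likelihood at sigma ~ 0 equals the
        closed-form likelihood without the random effect."""
        h = _toy_history()
        free = occ.fit_occupancy(h, [], [], random_intercept=False)
        nll_re, _ = occ.make_negloglik(h, [], [], random_intercept=True)
        theta = np.r_[free.psi_coefs, free.p_coefs, np.log(1e-8)]
        assert nll_re(theta) == pytest.approx(-free.loglik, abs=1e-6)

    def test_recovery_at_300_sites(self, small_stack):
        truth = syn.OccTruth(site_sd=0.5)
        hist_df, sc, svc, _ = syn.gen_detections(truth, small_stack, 300,
                                                 10, 42)
        h = occ.history_from_long(hist_df, sc, svc)
        fit = occ.fit_occupancy(h, ["canopy"], ["tree_density", "snow"])
        se = fit.se()
        truth_vec = [0.3, 0.5, -0.8, 0.4, -0.3]
        est = np.r_[fit.psi_coefs, fit.p_coefs]
        assert np.sum(np.abs(est - truth_vec) <= 2 * se) >= 4
        assert abs(fit.sigma_site - 0.5) < 0.3


class TestPsiCandidates:
    def test_three_structures(self):
        cands = occ.psi_candidates(["canopy", "tree_density"])
        assert len(cands) == 3

    def test_nesting(self):
        c1, c2, c3 = occ.psi_candidates(["canopy"])
        assert set(c1) <= set(c2) <= set(c3)


class TestGofAndSe:
    def test_correct_se_arithmetic(self):
        h = _toy_history()
        fit = occ.fit_occupancy(h, [], [], random_intercept=False)
        for c_hat, factor in [(1.0, 1.0), (4.0, 2.0), (2.25, 1.5),
                              (0.5, 1.0)]:
            fit.c_hat = c_hat
            assert np.allclose(fit.se_corrected(), fit.se() * factor)

    def test_correct_se_requires_gof(self):
        h = _toy_history()
        fit = occ.fit_occupancy(h, [], [], random_intercept=False)
        with pytest.raises(ValueError):
            occ.correct_se(fit)

    def test_mackenzie_bailey_deterministic(self, small_stack):
        truth = syn.OccTruth(site_sd=0.0)
        hist_df, sc, svc, _ = syn.gen_detections(truth, small_stack, 60, 6, 9)
        h = occ.history_from_long(hist_df, sc, svc)
        fit = occ.fit_occupancy(h, [], ["snow"], random_intercept=False)
        g1 = occ.mackenzie_bailey(fit, h, n_boot=3, seed=11)
        g2 = occ.mackenzie_bailey(fit, h, n_boot=3, seed=11)
        assert g1.c_hat == g2.c_hat and g1.gof_p == g2.gof_p

    def test_overdispersed_data_raises_c_hat(self, small_stack):
        """Extra-binomial site noise should push c_hat above 1."""
        truth = syn.OccTruth(psi_coefs={"(Intercept)": 0.5},
                             p_coefs={"(Intercept)": -0.3}, site_sd=2.5)
        hist_df, sc, svc, _ = syn.gen_detections(truth, small_stack, 150,
                                                 8, 13)
        h = occ.history_from_long(hist_df, sc, svc)
        # misspecified fit: ignores the site heterogeneity
        fit = occ.fit_occupancy(h, [], [], random_intercept=False)
        gof = occ.mackenzie_bailey(fit, h, n_boot=30, seed=2)
        assert gof.c_hat > 1.0


def test_psi_hat_at_least_naive_occupancy(small_stack):
    truth = syn.OccTruth(site_sd=0.0)
    hist_df, sc, svc, _ = syn.gen_detections(truth, small_stack, 200, 6, 21)
    h = occ.history_from_long(hist_df, sc, svc)
    fit = occ.fit_occupancy(h, [], [], random_intercept=False)
    naive = np.nanmax(h.y, axis=1).mean()
    assert expit(fit.psi_coefs[0]) >= naive - 1e-6
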