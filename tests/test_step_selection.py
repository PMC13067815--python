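"""GPS hygiene, step construction, conditional logit, movement kernels."""

import datetime as dt
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from harescape import step_selection as ssel
from harescape import synthetic_data as syn


def _fix_table(times_h, hare="h1", winter=2022, xy=None):
    base = dt.datetime(2022, 1, 1)
    n = len(times_h)
    if xy is None:
        xy = [(100.0 * i, 50.0 * i) for i in range(n)]
    return pd.DataFrame({
        "hare_id": hare, "winter": winter,
        "timestamp": [base + dt.timedelta(hours=h) for h in times_h],
        "x": [p[0] for p in xy], "y": [p[1] for p in xy],
        "hdop": 1.0, "n_sat": 8})


class TestFilterFixes:
    def test_boundary_values_kept(self):
        df = pd.DataFrame({"hdop": [5.0], "n_sat": [3]})
        assert len(ssel.filter_fixes(df)) == 1

    def test_violations_dropped(self):
        df = pd.DataFrame({"hdop": [5.1, 1.0], "n_sat": [8, 2]})
        assert len(ssel.filter_fixes(df)) == 0

    def test_mixed_table_hand_count(self):
        hdop = [1, 2, 5.0, 5.5, 3, 6.1, 2, 2, 4, 1]
        nsat = [4, 3, 3, 8, 2, 9, 5, 6, 7, 3]
        df = pd.DataFrame({"hdop": hdop, "n_sat": nsat})
        out = ssel.filter_fixes(df)
        assert len(out) == 7
        assert list(out.index) == [0, 1, 2, 6, 7, 8, 9]  # order preserved


class TestRegularize:
    def test_clean_4h_track(self):
        steps = ssel.regularize(_fix_table([0, 4, 8, 12]))
        assert len(steps) == 3
        assert [s.hour for s in pd.to_datetime(steps["t_end"])] == [4, 8, 12]

    def test_hourly_fixes_greedy_trace(self):
        """Hourly fixes with a [2, 6] h window: earliest qualifying gap is
        2 h, so the trace is (0->2), (2->4)."""
        steps = ssel.regularize(_fix_table([0, 1, 2, 3, 4]))
        got = [(pd.Timestamp(a).hour, pd.Timestamp(b).hour)
               for a, b in zip(steps["t_start"], steps["t_end"])]
        assert got == [(0, 2), (2, 4)]

    def test_gap_outside_window_fragments(self):
        steps = ssel.regularize(_fix_table([0, 7]))
        assert len(steps) == 0

    def test_turn_angle_resets_across_fragments(self):
        steps = ssel.regularize(_fix_table([0, 4, 8, 20, 24, 28]))
        assert len(steps) == 4
        # first step of each fragment has undefined turn angle
        frag_first = steps.drop_duplicates("fragment")["ta"]
        assert frag_first.isna().all()
        assert steps["ta"].notna().sum() == 2


class TestTentativeKernel:
    def test_gamma_shape_recovery(self, rng):
        sl = rng.gamma(2.0, 50.0, 5000)
        ta = rng.vonmises(0, 1.0, 5000)
        steps = pd.DataFrame({"sl": sl, "ta": ta})
        k = ssel.fit_tentative(steps)
        assert 1.9 <= k.shape <= 2.1

    def test_uniform_angles_zero_kappa(self, rng):
        steps = pd.DataFrame({"sl": rng.gamma(2, 50, 100),
                              "ta": rng.uniform(-np.pi, np.pi, 100)})
        assert ssel.fit_tentative(steps).kappa < 0.2

    def test_scale_equivariance(self, rng):
        sl = rng.gamma(2.0, 50.0, 2000)
        ta = rng.vonmises(0, 1.0, 2000)
        k1 = ssel.fit_tentative(pd.DataFrame({"sl": sl, "ta": ta}))
        k2 = ssel.fit_tentative(pd.DataFrame({"sl": 2 * sl, "ta": ta}))
        assert k2.scale == pytest.approx(2 * k1.scale, rel=1e-6)
        assert k2.shape == pytest.approx(k1.shape, rel=1e-6)

    def test_degenerate_lengths_rejected(self):
        steps = pd.DataFrame({"sl": np.full(30, 10.0),
                              "ta": np.zeros(30)})
        with pytest.raises(ValueError):
            ssel.fit_tentative(steps)


class TestSampleRandomSteps:
    def test_deterministic_per_seed(self):
        k = ssel.MovementKernel(2.0, 40.0, 0.5)
        a = ssel.sample_random_steps((0, 0), 0.3, k, m=10, seed=5)
        b = ssel.sample_random_steps((0, 0), 0.3, k, m=10, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_mean_length_matches_kernel(self):
        k = ssel.MovementKernel(2.0, 40.0, 0.5)
        _, _, sl, _ = ssel.sample_random_steps((0, 0), 0.0, k, m=100_000,
                                               seed=1)
        assert sl.mean() == pytest.approx(80.0, rel=0.01)

    def test_high_kappa_bearings_follow_previous(self):
        k = ssel.MovementKernel(2.0, 40.0, 1e6)
        x, y, _, ta = ssel.sample_random_steps((0, 0), 0.7, k, m=100, seed=2)
        assert np.abs(ta).max() < 0.01
        assert np.allclose(np.arctan2(y, x), 0.7, atol=0.01)


def _toy_cases():
    # 3 strata x 2 alternatives, single covariate
    return pd.DataFrame({
        "stratum": [0, 0, 1, 1, 2, 2],
        "case": [True, False, True, False, True, False],
        "z": [1.0, 0.0, 0.8, 0.4, 0.2, 1.0]})


class TestFitClogit:
    def test_matches_grid_search_oracle(self):
        cases = _toy_cases()
        fit = ssel.fit_clogit(cases, ["z"], standardize=False)
        grid = np.linspace(-3, 3, 20001)
        z = cases["z"].to_numpy().reshape(3, 2)

        def ll(b):
            eta = b * z
            return (eta[:, 0] - np.log(np.exp(eta).sum(axis=1))).sum()

        best = grid[np.argmax([ll(b) for b in grid])]
        assert fit.coefs[0] == pytest.approx(best, abs=1e-3)

    def test_stratum_constant_covariate_dropped(self):
        cases = _toy_cases()
        cases["const"] = cases["stratum"].map({0: 5.0, 1: 2.0, 2: 9.0})
        with pytest.warns(UserWarning, match="stratum-constant"):
            fit = ssel.fit_clogit(cases, ["z", "const"], standardize=False)
        assert fit.terms == ["z"]
        base = ssel.fit_clogit(_toy_cases(), ["z"], standardize=False)
        assert fit.loglik == pytest.approx(base.loglik, abs=1e-10)

    def test_invariant_to_alternative_order(self):
        cases = _toy_cases()
        fit1 = ssel.fit_clogit(cases, ["z"], standardize=False)
        shuffled = cases.iloc[[1, 0, 2, 3, 5, 4]].reset_index(drop=True)
        fit2 = ssel.fit_clogit(shuffled, ["z"], standardize=False)
        assert fit2.coefs[0] == pytest.approx(fit1.coefs[0], abs=1e-9)

    def test_matches_r_survival_clogit(self, tmp_path):
        """Cross-check against the conditional-logit fit in R survival."""
        rng = np.random.default_rng(42)
        n_strata, m = 40, 5
        z1 = rng.normal(size=(n_strata, m + 1))
        z2 = rng.normal(size=(n_strata, m + 1))
        beta = np.array([0.8, -0.5])
        eta = 0.8 * z1 - 0.5 * z2
        pick = np.array([rng.choice(m + 1, p=np.exp(e) / np.exp(e).sum())
                         for e in eta])
        # reorder so the chosen alternative is the "observed" first row
        rows = []
        for s in range(n_strata):
            order = [pick[s]] + [a for a in range(m + 1) if a != pick[s]]
            for rank, a in enumerate(order):
                rows.append((s, rank == 0, z1[s, a], z2[s, a]))
        cases = pd.DataFrame(rows, columns=["stratum", "case", "z1", "z2"])
        fit = ssel.fit_clogit(cases, ["z1", "z2"], standardize=False)
        csv = tmp_path / "cases.csv"
        cases.assign(case=cases["case"].astype(int)).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(survival))
            d <- read.csv("{csv}")
            f <- clogit(case ~ z1 + z2 + strata(stratum), data = d)
            cat(sprintf("%.8f %.8f", coef(f)[1], coef(f)[2]))
        """)
        try:
            out = subprocess.run(["Rscript", "-e", script], check=True,
                                 capture_output=True, text=True, timeout=120)
        except (FileNotFoundError, subprocess.SubprocessError):
            pytest.skip("Rscript with survival unavailable")
        r_coefs = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(fit.coefs, r_coefs, atol=1e-4)

    def test_recovery_from_generator(self, small_stack):
        truth = syn.SsfTruth()
        fixes, info = syn.gen_tracks(truth, small_stack, 15, 120, 99)
        steps = ssel.regularize(ssel.filter_fixes(fixes))
        tent = ssel.fit_tentative(steps)
        cases = ssel.build_strata(steps, tent, small_stack, m=10, seed=1)
        terms = sorted(truth.betas) + ["log_sl", "cos_ta"]
        fit = ssel.fit_clogit(cases, terms)
        raw = fit.coefs_raw()
        se = dict(zip(fit.terms, fit.se()))
        for name, b_std in truth.betas.items():
            b_raw = b_std / info["scaling"][name][1]
            se_raw = se[name] / fit.scaling[name][1]
            assert abs(raw[name] - b_raw) < 2.5 * se_raw


class TestCandidateModels:
    def test_pool_of_three_gives_seven(self):
        cands = ssel.candidate_models_ssf(["a", "b"], ["i1", "i2", "i3"])
        assert len(cands) == 7

    def test_empty_pool_base_only(self):
        assert ssel.candidate_models_ssf(["a"], []) == [["a"]]

    def test_movement_component_shared(self):
        base = ["canopy", "log_sl", "cos_ta", "log_sl:snow"]
        cands = ssel.candidate_models_ssf(base, ["canopy:snow"])
        for c in cands:
            assert {"log_sl", "cos_ta", "log_sl:snow"} <= set(c)


class TestSelectionFreeKernel:
    def test_zero_movement_betas_identity(self):
        tent = ssel.MovementKernel(2.0, 40.0, 0.5)
        fit = ssel.SsfFit(terms=["canopy"], coefs=np.array([0.7]),
                          loglik=-1.0, aicc=2.0, n_strata=10)
        k = ssel.selection_free_kernel(fit, tent)
        assert (k.shape, k.scale, k.kappa) == (2.0, 40.0, 0.5)

    def test_additive_update(self):
        tent = ssel.MovementKernel(2.0, 40.0, 0.5)
        fit = ssel.SsfFit(
            terms=["log_sl", "cos_ta", "log_sl:snow"],
            coefs=np.array([0.5, 0.2, -0.1]), loglik=-1.0, aicc=2.0,
            n_strata=10)
        k0 = ssel.selection_free_kernel(fit, tent)
        assert k0.shape == pytest.approx(2.5)
        assert k0.scale == pytest.approx(40.0)
        assert k0.kappa == pytest.approx(0.7)
        k1 = ssel.selection_free_kernel(fit, tent, env={"snow": 2.0})
        assert k1.shape == pytest.approx(2.3)

    def test_invalid_shape_raises(self):
        tent = ssel.MovementKernel(0.5, 40.0, 0.5)
        fit = ssel.SsfFit(terms=["log_sl"], coefs=np.array([-1.0]),
                          loglik=-1.0, aicc=2.0, n_strata=10)
        with pytest.raises(ValueError, match="shape"):
            ssel.selection_free_kernel(fit, tent)

    def test_median_matches_importance_reweighted_draws(self, rng):
        """Gamma(k0 + b, theta) equals gamma(k0, theta) tilted by sl^b."""
        from scipy.stats import gamma as gd
        k0, theta, b = 2.0, 50.0, 0.5
        draws = rng.gamma(k0, theta, 1_000_000)
        w = draws**b
        order = np.argsort(draws)
        cw = np.cumsum(w[order])
        med_emp = draws[order][np.searchsorted(cw, 0.5 * cw[-1])]
        med_kernel = gd.ppf(0.5, k0 + b, scale=theta)
        assert med_kernel == pytest.approx(med_emp, rel=0.01)


class TestBootstrapSsf:
    @pytest.fixture()
    def sim(self, small_stack):
        truth = syn.SsfTruth()
        fixes, info = syn.gen_tracks(truth, small_stack, 10, 80, 5)
        steps = ssel.regularize(ssel.filter_fixes(fixes))
        return truth, info, steps

    def test_take_all_single_fit(self, sim, small_stack):
        truth, info, steps = sim
        base = sorted(truth.betas) + ["log_sl", "cos_ta"]
        boot = ssel.bootstrap_ssf(steps, small_stack, [base], n_boot=1,
                                  seed=7, take_all=True)
        assert boot.n_boot == 1
        assert set(boot.coef_mean) == set(base)

    def test_identical_candidates_split_weight(self, sim, small_stack):
        truth, info, steps = sim
        base = sorted(truth.betas) + ["log_sl", "cos_ta"]
        boot = ssel.bootstrap_ssf(steps, small_stack, [base, list(base)],
                                  n_boot=3, seed=7)
        w = list(boot.mean_weights.values())
        assert w[0] == pytest.approx(0.5, abs=1e-9)
        assert w[1] == pytest.approx(0.5, abs=1e-9)

    def test_threshold_excludes_small_units(self, sim, small_stack):
        truth, info, steps = sim
        short = steps.groupby("hare_id").head(5)
        with pytest.raises(ValueError, match="threshold"):
            ssel.bootstrap_ssf(short, small_stack,
                               [sorted(truth.betas) + ["log_sl", "cos_ta"]],
                               n_boot=2, n_obs=25, seed=1)


def test_stratum_constant_addition_leaves_likelihood(rng):
    """The conditional likelihood ignores stratum-constant covariates."""
    cases = _toy_cases()
    fit1 = ssel.fit_clogit(cases, ["z"], standardize=False)
    shifted = cases.copy()
    shifted["z"] = shifted["z"] + shifted["stratum"].map({0: 3.0, 1: -1.0,
                                                          2: 0.5})
    fit2 = ssel.fit_clogit(shifted, ["z"], standardize=False)
    assert fit2.coefs[0] == pytest.approx(fit1.coefs[0], abs=1e-6)
    assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-8)


def test_assign_diel_phase_counts_partition(wisconsin):
    fixes = _fix_table(list(range(0, 48, 4)))
    steps = ssel.regularize(fixes)
    phase = ssel.assign_diel_phase(steps, wisconsin)
    assert set(phase) <= {"night", "day"}
    assert len(phase) == len(steps)
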