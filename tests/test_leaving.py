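import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchforage import (
    FitError,
    FixationTrace,
    GeneratorParams,
    LeaveProfile,
    PatchLeavingModel,
    TaskConfig,
    ValueProfile,
    aic,
    akaike_weights,
    compare_models,
    leave_probability_profile,
    relative_likelihoods,
    simulate_sessions,
    value_profile,
)
from patchforage.leaving import _gaussian_ll
from patchforage.experiments import RECOVERY_GENERATORS, hyperbolic_k_recovery

from conftest import make_trial


def bin_starts(config):
    return np.arange(config.n_analysis_bins) * config.bin_width_s


def decaying_value(config, tau=1.3):
    r = np.exp(-bin_starts(config) / tau)
    return ValueProfile(bin_starts(config), r / r.max())


class TestLeaveProfile:
    def test_binning_example(self, config):
        trials = [
            make_trial(environment_index=i, residence_time_s=r)
            for i, r in enumerate([0.15, 0.25, 0.25, 4.95])
        ]
        profile = leave_probability_profile(trials, 1.0, config)
        assert profile.p_leave[1] == pytest.approx(0.25)
        assert profile.p_leave[2] == pytest.approx(0.5)
        assert profile.p_leave[49] == pytest.approx(0.25)
        assert profile.p_leave.sum() == pytest.approx(1.0)
        assert profile.n_trials == 4

    def test_no_qualifying_trials_is_an_error(self, config):
        trials = [make_trial(residence_time_s=6.0)]
        with pytest.raises(ValueError, match="travel time 1"):
            leave_probability_profile(trials, 1.0, config)

    def test_mass_is_included_over_total(self, config):
        trials = [
            make_trial(environment_index=i, residence_time_s=r)
            for i, r in enumerate([0.5, 1.5, 7.0, 9.0])
        ]
        trials.append(
            make_trial(environment_index=9, residence_time_s=15.0, left_by_choice=False)
        )
        profile = leave_probability_profile(trials, 1.0, config)
        # timeouts excluded entirely; 2 of 4 by-choice leaves fall in-window
        assert profile.n_trials == 4
        assert profile.p_leave.sum() == pytest.approx(0.5)


class TestValueProfile:
    def test_uniform_looking_gives_all_ones(self, config):
        traces = [FixationTrace(("s", 0, i + 1), ((0, 15000),)) for i in range(3)]
        vp = value_profile(traces, config)
        assert np.allclose(vp.r, 1.0)

    def test_single_bin_looking(self, config):
        vp = value_profile([FixationTrace(("s", 0, 1), ((0, 100),))], config)
        assert vp.r[0] == 1.0
        assert np.allclose(vp.r[1:], 0.0)

    def test_matches_interval_overlap_oracle(self, config):
        rng = np.random.default_rng(8)
        traces = []
        for i in range(5):
            edges = np.sort(rng.choice(np.arange(1, 5000), size=6, replace=False))
            traces.append(
                FixationTrace(
                    ("s", 0, i + 1),
                    tuple((int(edges[j]), int(edges[j + 1])) for j in range(0, 6, 2)),
                )
            )
        vp = value_profile(traces, config)
        totals = np.zeros(50)
        for tr in traces:
            for s, e in tr.intervals:
                for b in range(50):
                    totals[b] += max(0, min(e, (b + 1) * 100) - max(s, b * 100))
        assert np.allclose(vp.r, totals / totals.max())

    def test_all_zero_looking_rejected(self, config):
        with pytest.raises(ValueError):
            value_profile([FixationTrace(("s", 0, 1), ())], config)


class TestLinearFits:
    def test_time_only_exact_interpolation(self, config):
        t = bin_starts(config) + 0.05
        coeffs = (0.02, -0.004, 0.0002)
        p = coeffs[0] + coeffs[1] * t + coeffs[2] * t**2
        profile = LeaveProfile(1.0, bin_starts(config), p, 100)
        res = PatchLeavingModel(profile, decaying_value(config), "time_only", config).fit()
        assert res.params["b0"] == pytest.approx(coeffs[0], abs=1e-10)
        assert res.params["b1"] == pytest.approx(coeffs[1], abs=1e-10)
        assert res.params["b2"] == pytest.approx(coeffs[2], abs=1e-10)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)

    def test_value_and_time_recovers_generating_coefficients(self, config):
        value = decaying_value(config)
        t = bin_starts(config) + 0.05
        b = (0.005, 0.025, 0.002, 0.0003)
        p = b[0] + b[1] * value.r + b[2] * t + b[3] * t**2
        profile = LeaveProfile(1.0, bin_starts(config), p, 100)
        res = PatchLeavingModel(profile, value, "value_and_time", config).fit()
        for name, truth in zip(("b0", "b1", "b2", "b3"), b):
            assert res.params[name] == pytest.approx(truth, abs=1e-9)
        assert res.k == 4
        assert res.aic == pytest.approx(-2 * res.llf + 8)

    def test_constant_value_profile_is_rank_deficient(self, config):
        flat = ValueProfile(bin_starts(config), np.ones(config.n_analysis_bins))
        profile = LeaveProfile(1.0, bin_starts(config), np.full(50, 0.01), 100)
        for variant in ("value_and_time", "value_only"):
            with pytest.raises(FitError, match="rank-deficient"):
                PatchLeavingModel(profile, flat, variant, config).fit()

    def test_nested_models_cannot_beat_the_full_model(self, config):
        """LL(value_and_time) >= max(LL(time_only), LL(value_only)) always."""
        rng = np.random.default_rng(4)
        value = decaying_value(config)
        for _ in range(20):
            p = rng.uniform(0, 0.018, size=50)
            profile = LeaveProfile(1.0, bin_starts(config), p, 200)
            fits = {
                v: PatchLeavingModel(profile, value, v, config).fit()
                for v in ("value_and_time", "time_only", "value_only")
            }
            assert fits["value_and_time"].llf >= fits["time_only"].llf - 1e-9
            assert fits["value_and_time"].llf >= fits["value_only"].llf - 1e-9


class TestHyperbolicFit:
    def test_noiseless_recovery(self, config):
        assert hyperbolic_k_recovery(2.0, 3.0) == pytest.approx(2.0, rel=1e-9)

    def test_k_zero_when_profile_equals_value(self, config):
        r = np.zeros(50)
        r[0] = 1.0
        value = ValueProfile(bin_starts(config), r)
        profile = LeaveProfile(3.0, bin_starts(config), r.copy(), 100)
        res = PatchLeavingModel(profile, value, "hyperbolic", config).fit()
        assert res.params["k"] == 0.0

    def test_fitted_k_declines_with_travel_on_mvt_like_data(self, config):
        """Leaving later at longer travels maps to smaller per-travel discounting."""
        value = decaying_value(config)
        t_star = {1.0: 1.3, 3.0: 2.1, 5.0: 2.5, 7.0: 2.9}
        ks = []
        for travel, peak in t_star.items():
            p = np.zeros(50)
            p[int(peak / 0.1)] = 0.9
            profile = LeaveProfile(travel, bin_starts(config), p, 100)
            res = PatchLeavingModel(profile, value, "hyperbolic", config).fit()
            ks.append(res.params["k"])
        assert all(a > b for a, b in zip(ks, ks[1:]))


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "ll, k, expected",
        [(159.248, 4, -310.496), (164.600, 4, -321.200), (0.0, 0, 0.0)],
    )
    def test_aic_arithmetic(self, ll, k, expected):
        assert aic(ll, k) == pytest.approx(expected, abs=1e-12)

    def test_equal_aics_split_weight(self):
        _, w = akaike_weights([-10.0, -10.0])
        assert w == pytest.approx([0.5, 0.5])

    def test_single_model_takes_all_weight(self):
        daic, w = akaike_weights([-321.2])
        assert daic == pytest.approx([0.0]) and w == pytest.approx([1.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-400, 400), min_size=2, max_size=6),
        st.floats(-50, 50),
    )
    def test_weights_normalized_and_shift_invariant(self, aics, shift):
        daic, w = akaike_weights(aics)
        assert daic.min() == 0.0
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((w > 0) & (w <= 1.0))
        _, w_shifted = akaike_weights([a + shift for a in aics])
        assert w_shifted == pytest.approx(w, abs=1e-9)

    def test_relative_likelihood_examples(self):
        assert np.allclose(relative_likelihoods([0.5, 0.5]), 1.0)
        r = relative_likelihoods([0.9, 0.1])
        assert r[0, 1] == pytest.approx(9.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=5))
    def test_relative_likelihoods_antisymmetric(self, weights):
        r = relative_likelihoods(weights)
        assert np.allclose(r * r.T, 1.0)
        assert np.allclose(np.diag(r), 1.0)

    def test_zero_weight_flags_infinity_without_raising(self):
        r = relative_likelihoods([0.5, 0.0])
        assert np.isinf(r[0, 1])

    def test_gaussian_ll_magnitude_regime(self):
        """RMSE ~0.009 over 50 bins lands LL in the 150-170 range."""
        resid = np.full(50, 0.009)
        assert 150 < _gaussian_ll(resid) < 170


class TestCompareModels:
    def test_table_schema(self, sim_dataset, config):
        comp = compare_models(*sim_dataset, config)
        assert list(comp.table.columns) == ["model", "travel", "LL", "K", "AIC", "dAIC", "w", "RMSE"]
        for travel in config.travel_times_s:
            sub = comp.table[comp.table["travel"] == travel]
            assert len(sub) == 4
            assert sub["dAIC"].min() == pytest.approx(0.0)
            assert sub["w"].sum() == pytest.approx(1.0)
            assert (sub["AIC"] == pytest.approx(-2 * sub["LL"] + 2 * sub["K"])) is not False

    def test_aic_identity_on_every_fit(self, sim_dataset, config):
        comp = compare_models(*sim_dataset, config)
        assert np.allclose(comp.table["AIC"], -2 * comp.table["LL"] + 2 * comp.table["K"])

    def test_fit_errors_annotated_and_others_reported(self, config):
        # a flat value profile makes the value-term designs collinear with the
        # intercept: value models fail, time_only and hyperbolic still fit
        import pandas as pd

        from patchforage import trials_to_frame

        rng = np.random.default_rng(13)
        trials = [
            make_trial(
                environment_index=i,
                travel_time_s=1.0,
                residence_time_s=float(rng.uniform(0.1, 4.9)),
            )
            for i in range(200)
        ]
        fixations = [FixationTrace(t.key, ((0, 15000),)) for t in trials]
        comp = compare_models(trials_to_frame(trials), fixations, config,
                              travel_times_s=(1.0,))
        assert comp.errors
        assert all(name in ("value_and_time", "value_only") for name, _ in comp.errors)
        assert set(comp.table["model"]) == {"time_only", "hyperbolic"}

    def test_policy_separation(self, config):
        """Hazard-rule data and hyperbolic-rule data pick different winners."""
        winners = {}
        for gen in ("value_and_time", "hyperbolic"):
            params = GeneratorParams(
                n_environments=100, seed=17, **RECOVERY_GENERATORS[gen]
            )
            comp = compare_models(*simulate_sessions(params, config), config)
            winners[gen] = comp.total_aic().idxmin()
        assert winners["value_and_time"] != winners["hyperbolic"]
        assert winners["value_and_time"] == "value_and_time"

    def test_summary_renders(self, sim_dataset, config):
        comp = compare_models(*sim_dataset, config)
        text = comp.summary()
        assert "value_and_time" in text and "RMSE" in text
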