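"""Least-squares fitting, the 60 % validity window, and the metric set."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import curve_fit

import releasefit as rf
from releasefit.errors import (
    DomainError,
    InsufficientDataError,
    UndefinedStatisticError,
)


def curve_from(qt, times=None, drug="x"):
    times = times if times is not None else np.arange(1.0, len(qt) + 1)
    return rf.ReleaseCurve(drug, times, np.asarray(qt, float))


class TestKpDomainRestriction:
    def test_prefix_below_cutoff_retained(self):
        kept = rf.restrict_kp_domain(curve_from([10, 30, 55, 70, 80]))
        assert len(kept) == 3

    def test_curve_never_reaching_cutoff_kept_whole(self):
        kept = rf.restrict_kp_domain(curve_from([10, 20, 30]))
        assert len(kept) == 3

    def test_truncation_at_first_crossing_is_permanent(self):
        # later sub-60 points after the crossing are not re-admitted
        kept = rf.restrict_kp_domain(curve_from([10, 65, 50, 55]))
        assert len(kept) == 1
        assert kept.qt[0] == 10

    def test_all_points_at_or_above_cutoff_rejected(self):
        with pytest.raises(InsufficientDataError):
            rf.restrict_kp_domain(curve_from([60, 70, 80]))

    def test_kp_fit_needs_three_surviving_points(self):
        with pytest.raises(InsufficientDataError):
            rf.fit_model(curve_from([10, 65, 50, 55]), "korsmeyer_peppas")


class TestRoundTripRecovery:
    GRID = np.arange(100.0, 3001.0, 100.0)

    @pytest.mark.parametrize(
        "model, params, rtol",
        [
            ("zero_order", (0.00363, 7.7436), 1e-6),
            ("higuchi", (0.5086, -0.1951), 1e-6),
            ("korsmeyer_peppas", (0.2575, 0.6062), 1e-4),
            ("first_order", (-59.78837, -0.00017754, 61.99435), 1e-4),
        ],
    )
    def test_noiseless_data_recovers_generating_parameters(self, model, params, rtol):
        q = rf.evaluate_model(model, params, self.GRID)
        fit = rf.fit_model(rf.ReleaseCurve("x", self.GRID, q), model)
        np.testing.assert_allclose(fit.params, params, rtol=rtol)
        assert fit.rss == pytest.approx(0.0, abs=1e-8)
        assert fit.adj_r_square == pytest.approx(1.0, abs=1e-10)
        assert fit.converged

    def test_flat_curve_degenerates_gracefully(self):
        fit = rf.fit_model(curve_from([5.0] * 6), "zero_order")
        assert fit.params[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.params[1] == pytest.approx(5.0)
        assert np.isnan(fit.adj_r_square)  # TSS = 0: statistic undefined

    @given(slope=st.floats(1e-3, 0.08), intercept=st.floats(-2.0, 20.0))
    def test_linear_models_recover_random_parameters(self, slope, intercept):
        t = np.linspace(10.0, 1000.0, 20)
        for model, q in (
            ("zero_order", slope * t + intercept),
            ("higuchi", slope * np.sqrt(t) + intercept),
        ):
            fit = rf.fit_model(rf.ReleaseCurve("x", t, q), model)
            np.testing.assert_allclose(
                fit.params, [slope, intercept], rtol=1e-6, atol=1e-9
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_power_law_recovers_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        K = rng.uniform(0.1, 10.0)
        n = rng.uniform(0.2, 0.9)
        t_max = (50.0 / K) ** (1.0 / n)  # keep the curve below the KP window
        t = np.geomspace(t_max / 100.0, t_max, 15)
        fit = rf.fit_model(
            rf.ReleaseCurve("x", t, K * t**n), "korsmeyer_peppas"
        )
        np.testing.assert_allclose(fit.params, [K, n], rtol=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_exponential_recovers_random_parameters(self, seed):
        rng = np.random.default_rng(100 + seed)
        K1 = rng.uniform(-70.0, -20.0)
        a = -(10.0 ** rng.uniform(-4.0, -2.0))
        b1 = -K1 * rng.uniform(1.05, 1.5)
        t = np.linspace(0.0, 3.0 / abs(a), 20)
        q = rf.evaluate_model("first_order", (K1, a, b1), t)
        fit = rf.fit_model(rf.ReleaseCurve("x", t, q), "first_order")
        np.testing.assert_allclose(fit.params, [K1, a, b1], rtol=1e-4)

    def test_closed_form_agrees_with_iterative_optimizer(self):
        rng = np.random.default_rng(7)
        t = np.linspace(10.0, 2000.0, 30)
        q = 0.02 * t + 5.0 + rng.normal(0, 1.0, t.size)
        closed = rf.fit_model(rf.ReleaseCurve("x", t, q), "zero_order").params
        popt, _ = curve_fit(
            lambda tt, k, b: k * tt + b, t, q, p0=closed,
            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        np.testing.assert_allclose(closed, popt, rtol=1e-9)

    def test_adj_r_square_invariant_under_time_rescaling(self):
        rng = np.random.default_rng(11)
        t = np.linspace(10.0, 2000.0, 30)
        q = 0.02 * t + 5.0 + rng.normal(0, 1.0, t.size)
        base = rf.fit_model(rf.ReleaseCurve("x", t, q), "zero_order")
        shifted = rf.fit_model(rf.ReleaseCurve("x", 2.0 * t + 5.0, q), "zero_order")
        assert shifted.adj_r_square == pytest.approx(base.adj_r_square, rel=1e-12)
        hig = rf.fit_model(rf.ReleaseCurve("x", t, 0.5 * np.sqrt(t) + q * 0.01), "higuchi")
        hig4 = rf.fit_model(
            rf.ReleaseCurve("x", 4.0 * t, 0.5 * np.sqrt(t) + q * 0.01), "higuchi"
        )
        assert hig4.adj_r_square == pytest.approx(hig.adj_r_square, rel=1e-12)

    def test_linearized_mode_matches_loglog_regression(self):
        t = np.geomspace(5.0, 500.0, 12)
        q = 0.5 * t**0.6
        fit = rf.fit_model(
            rf.ReleaseCurve("x", t, q), "korsmeyer_peppas",
            rf.FitOptions(fit_scale="linearized"),
        )
        np.testing.assert_allclose(fit.params, [0.5, 0.6], rtol=1e-10)


class TestMetrics:
    def test_adjusted_r_square_reference_points(self):
        obs = np.array([1.0, 2.0, 3.0, 5.0])
        assert rf.adj_r_square(obs, obs, 2) == pytest.approx(1.0)
        assert rf.adj_r_square(obs, np.full(4, obs.mean()), 1) == pytest.approx(0.0)
        # frozen brute-force arithmetic oracle
        assert rf.adj_r_square(obs, [1.1, 1.9, 3.2, 4.8], 2) == pytest.approx(
            0.9828571428571429, rel=1e-12
        )

    def test_adjusted_r_square_undefined_for_flat_observations(self):
        with pytest.raises(UndefinedStatisticError):
            rf.adj_r_square([2.0, 2.0, 2.0, 2.0], [2.0, 2.1, 1.9, 2.0], 1)

    def test_pearson_r_reference_points(self):
        obs = np.array([1.0, 2.0, 4.0])
        assert rf.pearson_r(obs, obs) == pytest.approx(1.0)
        assert rf.pearson_r(obs, -obs) == pytest.approx(-1.0)
        assert rf.pearson_r(obs, [2.0, 3.0, 5.0]) == pytest.approx(1.0)
        with pytest.raises(UndefinedStatisticError):
            rf.pearson_r(obs, [1.0, 1.0, 1.0])

    def test_reduced_chi_square_reproduces_printed_ratios(self):
        # printed (RSS, reduced χ²) pairs imply integer dof
        assert rf.reduced_chi_sq(137.58277, 34, 3) == pytest.approx(4.43815, abs=5.1e-6)
        assert rf.reduced_chi_sq(93.76934, 30, 2) == pytest.approx(3.34891, abs=5.1e-6)
        assert rf.reduced_chi_sq(0.0, 10, 2) == 0.0
        with pytest.raises(DomainError):
            rf.reduced_chi_sq(1.0, 3, 3)

    def test_reduced_chi_square_times_dof_equals_rss(self, simple_curve):
        for model in rf.MODEL_ORDER:
            fit = rf.fit_model(simple_curve, model)
            assert fit.reduced_chi_sq * fit.dof == pytest.approx(fit.rss, rel=1e-12)


def test_degrees_of_freedom_consistency_across_published_tables():
    """Every published (RSS, reduced χ²) pair divides to an integer dof and
    divides back to the printed value at its printed precision."""
    checked = 0
    for (drug, model), fx in rf.FIXTURES.items():
        if fx.reduced_chi_sq is None:
            continue
        ratio = fx.rss / fx.reduced_chi_sq
        dof = round(ratio)
        assert abs(ratio - dof) < 0.01, (drug, model)
        n_params = rf.get_model(model).n_params
        # one unit in the last printed digit (some table values are truncated)
        decimals = len(repr(fx.reduced_chi_sq).split(".")[1])
        value = rf.reduced_chi_sq(fx.rss, dof + n_params, n_params)
        assert value == pytest.approx(fx.reduced_chi_sq, abs=1.02 * 10.0**-decimals), (
            drug,
            model,
        )
        checked += 1
    assert checked == 27  # three metric-bearing model blocks × nine drugs
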