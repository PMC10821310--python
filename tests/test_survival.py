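"""Parametric survival curves, transition probabilities, and KM fitting."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.optimize import brentq

from esccea.survival import (FAMILIES, FitError, KMPoints, ParametricSurvival,
                             SurvivalDomainError, fit_all_families,
                             fit_parametric, fit_report, median_survival,
                             proportional_hazards, select_model, survival_at,
                             transition_probability)

WEIBULL_OS_SERP = ParametricSurvival("weibull", (0.02617, 1.16846))

EXAMPLE_MODELS = [
    ParametricSurvival("exponential", (0.08,)),
    ParametricSurvival("weibull", (0.05, 1.3)),
    ParametricSurvival("weibull", (0.10927, 0.97361)),
    ParametricSurvival("log-logistic", (8.0, 1.7)),
    ParametricSurvival("log-normal", (2.1, 0.8)),
    ParametricSurvival("gompertz", (0.03, 0.08)),
    ParametricSurvival("gompertz", (0.08, -0.02)),
]


class TestEvaluation:
    def test_survival_at_zero_is_one(self):
        for m in EXAMPLE_MODELS:
            assert survival_at(m, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_weibull_shape_one_reduces_to_exponential(self):
        m = ParametricSurvival("weibull", (0.1, 1.0))
        assert survival_at(m, 10) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_weibull_published_scale_shape_at_one_year(self):
        # direct evaluation of exp(-0.02617 * 12**1.16846)
        assert survival_at(WEIBULL_OS_SERP, 12) == pytest.approx(
            0.6204615420553503, abs=1e-9)

    @pytest.mark.parametrize("model", EXAMPLE_MODELS,
                             ids=lambda m: f"{m.family}{m.params}")
    def test_survival_is_monotone_and_bounded(self, model):
        t = np.linspace(0, 60, 400)
        s = model.survival(t)
        assert np.all(s >= 0) and np.all(s <= 1)
        assert np.all(np.diff(s) <= 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(SurvivalDomainError):
            WEIBULL_OS_SERP.survival(-1.0)

    @pytest.mark.parametrize("family,params", [
        ("weibull", (-0.1, 1.0)), ("weibull", (0.1, 0.0)),
        ("exponential", (0.0,)), ("log-normal", (1.0, -1.0)),
        ("gompertz", (-0.01, 0.1)), ("log-logistic", (0.0, 1.0)),
    ])
    def test_invalid_params_rejected(self, family, params):
        with pytest.raises(SurvivalDomainError):
            ParametricSurvival(family, params)


class TestTransitionProbability:
    def test_exponential_is_memoryless(self):
        m = ParametricSurvival("exponential", (0.1,))
        expected = 1 - math.exp(-0.1)
        for t in (1.0, 5.0, 40.0):
            assert transition_probability(m, t, 1.0) == pytest.approx(
                expected, rel=1e-12)

    def test_first_cycle_equals_cumulative_risk(self):
        m = ParametricSurvival("weibull", (0.05, 1.3))
        assert transition_probability(m, 2.0, 2.0) == pytest.approx(
            1 - m.survival(2.0), rel=1e-12)

    def test_published_weibull_second_cycle(self):
        # oracle: 1 - S(2)/S(1) at high precision
        assert transition_probability(WEIBULL_OS_SERP, 2.0, 1.0) == \
            pytest.approx(0.03212539213872427, abs=1e-9)

    @pytest.mark.parametrize("model", EXAMPLE_MODELS,
                             ids=lambda m: f"{m.family}{m.params}")
    def test_equals_conditional_survival_identity(self, model):
        for t in np.linspace(0.5, 48, 60):
            expected = 1 - model.survival(t) / model.survival(t - 0.5)
            assert transition_probability(model, t, 0.5) == pytest.approx(
                expected, abs=1e-12)

    @given(lam=st.floats(0.005, 0.3), gam=st.floats(0.3, 3.0),
           t=st.floats(0.5, 100.0), u=st.floats(0.01, 0.5))
    @settings(max_examples=200, derandomize=True)
    def test_weibull_identity_property(self, lam, gam, t, u):
        m = ParametricSurvival("weibull", (lam, gam))
        assume(m.survival(t + u) > 0)  # identity needs a non-underflowed tail
        p = m.transition_probability(t + u, u)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(1 - m.survival(t + u) / m.survival(t),
                                  abs=1e-12)

    @pytest.mark.parametrize("gam,trend", [(1.4, 1), (1.0, 0), (0.7, -1)])
    def test_shape_controls_hazard_trend(self, gam, trend):
        m = ParametricSurvival("weibull", (0.05, gam))
        tps = [m.transition_probability(t, 1.0) for t in range(1, 40)]
        diffs = np.diff(tps)
        if trend > 0:
            assert np.all(diffs > 0)
        elif trend < 0:
            assert np.all(diffs < 0)
        else:
            assert np.allclose(diffs, 0, atol=1e-15)

    def test_product_of_survivors_telescopes(self):
        m = ParametricSurvival("weibull", (0.05, 1.3))
        u, K = 0.46, 50
        prod = np.prod([1 - m.transition_probability(k * u, u)
                        for k in range(1, K + 1)])
        assert prod == pytest.approx(m.survival(K * u), abs=1e-10)

    def test_t_less_than_u_rejected(self):
        with pytest.raises(SurvivalDomainError):
            transition_probability(WEIBULL_OS_SERP, 0.5, 1.0)


class TestMedian:
    def test_exponential_closed_form(self):
        assert median_survival(ParametricSurvival("weibull", (math.log(2), 1.0))) \
            == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("params,expected", [
        ((0.02617, 1.16846), 16.514327481),   # intervention OS
        ((0.020542, 1.404457), 12.248843022),  # comparator OS
        ((0.10927, 0.97361), 6.669169756),     # intervention PFS
        ((0.0931, 1.32774), 4.535879725),      # comparator PFS
    ])
    def test_published_weibull_medians_months(self, params, expected):
        m = ParametricSurvival("weibull", params)
        assert median_survival(m) == pytest.approx(expected, rel=1e-8)

    @pytest.mark.parametrize("model", EXAMPLE_MODELS,
                             ids=lambda m: f"{m.family}{m.params}")
    def test_median_agrees_with_root_finding(self, model):
        # independent oracle: numerically invert S(t) = 1/2
        root = brentq(lambda t: model.survival(t) - 0.5, 1e-9, 1e4)
        assert median_survival(model) == pytest.approx(root, rel=1e-8)


class TestProportionalHazards:
    def test_power_relation(self):
        m = ParametricSurvival("weibull", (0.05, 1.3))
        scaled = proportional_hazards(m, 0.6)
        t = np.linspace(0.5, 40, 20)
        assert np.allclose(scaled.survival(t), m.survival(t) ** 0.6,
                           atol=1e-14)

    def test_invalid_hr_rejected(self):
        with pytest.raises(SurvivalDomainError):
            proportional_hazards(WEIBULL_OS_SERP, 0.0)


def _points_from(model, times):
    return KMPoints([(t, float(model.survival(t))) for t in times])


class TestFitting:
    def test_noise_free_weibull_recovered_exactly(self):
        truth = ParametricSurvival("weibull", (0.05, 1.3))
        fit = fit_parametric(_points_from(truth, range(1, 25)), "weibull")
        assert fit.model.params == pytest.approx(truth.params, abs=1e-6)
        assert fit.sse < 1e-20

    def test_exponential_data_gives_unit_weibull_shape(self):
        truth = ParametricSurvival("exponential", (0.08,))
        fit = fit_parametric(_points_from(truth, range(1, 25)), "weibull")
        assert fit.model.params[1] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("family,params", [
        ("exponential", (0.07,)),
        ("log-logistic", (9.0, 1.6)),
        ("log-normal", (2.2, 0.7)),
        ("gompertz", (0.03, 0.06)),
    ])
    def test_noise_free_other_families_recovered(self, family, params):
        truth = ParametricSurvival(family, params)
        times = np.linspace(1, 36, 36)
        fit = fit_parametric(_points_from(truth, times), family)
        assert fit.model.params == pytest.approx(params, rel=1e-4)

    def test_noisy_recovery_within_ten_percent(self):
        from esccea.synthetic import SyntheticScenario, generate_km_points
        truth = ParametricSurvival("weibull", (0.05, 1.3))
        scenario = SyntheticScenario(
            os_truth=truth, pfs_truth=truth,
            grid=np.linspace(0.6, 24, 40), digitization_noise_sd=0.01,
            seed=7)
        os_pts, _ = generate_km_points(scenario)
        fit = fit_parametric(os_pts, "weibull")
        assert fit.model.params[0] == pytest.approx(0.05, rel=0.10)
        assert fit.model.params[1] == pytest.approx(1.3, rel=0.10)

    def test_boundary_points_dropped(self):
        truth = ParametricSurvival("weibull", (0.05, 1.3))
        pts = KMPoints([(0.0, 1.0)] + [(t, float(truth.survival(t)))
                                       for t in range(1, 15)])
        fit = fit_parametric(pts, "weibull")
        assert fit.n_points == 14
        assert "dropped" in fit.notes

    def test_too_few_points_raise(self):
        with pytest.raises(FitError):
            fit_parametric(KMPoints([(1, 0.9), (2, 0.8)]), "weibull")

    def test_select_model_prefers_true_family(self):
        truth = ParametricSurvival("weibull", (0.05, 1.5))
        pts = _points_from(truth, np.linspace(1, 30, 30))
        best = select_model(fit_all_families(pts))
        assert best.model.family == "weibull"

    def test_select_model_minimal_aic_then_bic(self):
        mk = lambda aic, bic: type("F", (), {
            "aic": aic, "bic": bic,
            "model": ParametricSurvival("weibull", (0.1, 1.0))})()
        assert select_model([mk(10, 5), mk(12, 1)]).aic == 10
        assert select_model([mk(10, 7), mk(10, 5)]).bic == 5
        with pytest.raises(FitError):
            select_model([])

    def test_fit_report_sorted_by_aic(self):
        truth = ParametricSurvival("weibull", (0.05, 1.5))
        fits = fit_all_families(_points_from(truth, np.linspace(1, 30, 30)))
        rep = fit_report(fits)
        assert list(rep.columns) == ["family", "params", "n_points", "sse",
                                     "aic", "bic"]
        assert rep["aic"].is_monotonic_increasing
        assert rep.loc[0, "family"] == "weibull"


class TestKMPointsIO:
    def test_file_round_trip(self, tmp_path):
        truth = ParametricSurvival("weibull", (0.05, 1.3))
        pts = _points_from(truth, range(1, 20))
        path = tmp_path / "km.txt"
        pts.to_file(path)
        back = KMPoints.from_file(path)
        assert np.allclose(back.times, pts.times)
        assert np.allclose(back.survival, pts.survival)

    def test_comments_headers_and_commas_skipped(self, tmp_path):
        path = tmp_path / "km.csv"
        path.write_text("# digitized curve\ntime,survival\n1,0.95\n2,0.90\n")
        pts = KMPoints.from_file(path)
        assert pts.points == [(1.0, 0.95), (2.0, 0.90)]

    @pytest.mark.parametrize("bad", [
        [(2, 0.9), (1, 0.8)],          # times not increasing
        [(1, 0.8), (2, 0.9)],          # survival increasing
        [(1, 1.2)],                    # out of range
        [(-1, 0.5)],                   # negative time
    ])
    def test_invalid_point_sets_rejected(self, bad):
        with pytest.raises(ValueError):
            KMPoints(bad)
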