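"""Annual survival, life expectancy and predicted age structures."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from silersurv import (
    CONSTANT,
    SILER,
    AgeFrequencyData,
    SilerModel,
    SilerParams,
    SilerResults,
    age_specific_survival,
    hazard,
    life_expectancy,
    posterior_annual_survival,
    predict_age_frequencies,
)


class TestAgeSpecificSurvival:
    def test_constant_hazard_gives_constant_survival(self):
        p = SilerParams(a2=0.43078)
        for x in (0, 1, 5, 20):
            assert age_specific_survival(p, CONSTANT, x) == pytest.approx(0.65, abs=1e-4)

    def test_siler_ratio_matches_quadrature(self, siler_params):
        integral, _ = quad(
            lambda t: hazard(siler_params, SILER, t), 1.0, 2.0, epsabs=1e-12
        )
        assert age_specific_survival(siler_params, SILER, 1.0) == pytest.approx(
            math.exp(-integral), abs=1e-8
        )

    def test_no_mortality_means_certain_survival(self):
        p = SilerParams(a1=0, a2=0, a3=0)
        assert age_specific_survival(p, CONSTANT, 3.0) == 1.0


class TestLifeExpectancy:
    def test_printed_conversion(self):
        assert round(life_expectancy(0.65), 2) == 2.32

    def test_definition(self):
        assert life_expectancy(math.exp(-1.0)) == pytest.approx(1.0, rel=1e-12)
        assert life_expectancy(0.5) == pytest.approx(1.4427, abs=1e-4)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            life_expectancy(bad)

    def test_monotone_in_survival(self):
        s = np.linspace(0.05, 0.95, 19)
        le = [life_expectancy(v) for v in s]
        assert np.all(np.diff(le) > 0)


def _constant_results(a2_draws, a_draws=None, sigma=0.01):
    n = len(a2_draws)
    a_draws = np.full(n, 0.3) if a_draws is None else a_draws
    data = AgeFrequencyData(
        colony="c", ages=[0, 1, 2, 3], frequencies=[0.4, 0.3, 0.2, 0.1], n_total=100
    )
    m = SilerModel(data, CONSTANT)
    draws = np.column_stack([a_draws, a2_draws, np.full(n, sigma)])
    return SilerResults.from_draws(m, draws)


class TestPosteriorAnnualSurvival:
    def test_point_mass(self):
        res = _constant_results(np.full(100, 0.43078))
        s = posterior_annual_survival(res)
        assert s.mean == pytest.approx(0.65, abs=1e-4)
        assert s.upper - s.lower == pytest.approx(0.0, abs=1e-12)

    def test_transform_then_quantile_oracle(self):
        rng = np.random.default_rng(0)
        a2 = rng.normal(0.15, 0.001, size=20_000)
        res = _constant_results(a2)
        s = posterior_annual_survival(res)
        assert s.mean == pytest.approx(np.exp(-a2).mean(), rel=1e-12)
        lo, hi = np.percentile(np.exp(-a2), [2.5, 97.5])
        assert s.lower == pytest.approx(lo, rel=1e-9)
        assert s.upper == pytest.approx(hi, rel=1e-9)

    def test_zero_hazard_draw_maps_to_boundary(self):
        res = _constant_results(np.array([0.0, 0.1, 0.2] * 10))
        s = posterior_annual_survival(res)
        assert s.upper == pytest.approx(1.0)
        assert 0 < s.mean <= 1.0

    def test_non_constant_model_needs_an_age(self, siler_params):
        data = AgeFrequencyData(
            colony="c", ages=[0, 1, 2, 3], frequencies=[0.4, 0.3, 0.2, 0.1], n_total=9
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = SilerModel(data, SILER)
        from silersurv.model import _params_to_vector

        draws = np.tile(_params_to_vector(siler_params, SILER), (10, 1))
        res = SilerResults.from_draws(m, draws)
        with pytest.raises(ValueError, match="age"):
            posterior_annual_survival(res)
        s1 = posterior_annual_survival(res, age=1.0)
        expected = age_specific_survival(siler_params, SILER, 1.0)
        assert s1.mean == pytest.approx(expected, rel=1e-10)

    def test_jensen_gap_direction(self):
        # -1/ln(S) is convex in a2, so the mean of per-draw life
        # expectancies exceeds the plug-in at the posterior-mean survival
        rng = np.random.default_rng(1)
        a2 = rng.normal(0.3, 0.03, size=5_000)
        res = _constant_results(a2)
        per_draw = np.mean([-1.0 / np.log(np.exp(-v)) for v in a2])
        plug_in = res.life_expectancy()
        assert per_draw >= plug_in


class TestPredictAgeFrequencies:
    def test_point_mass_reduces_to_exponential(self):
        res = _constant_results(np.full(50, 0.2), a_draws=np.full(50, 1.0))
        pred = predict_age_frequencies(res, max_age=10, n_colony=1.0)
        np.testing.assert_allclose(
            pred.table["mean"], np.exp(-0.2 * np.arange(11)), rtol=1e-12
        )

    def test_log_linear_for_point_mass(self):
        res = _constant_results(np.full(50, 0.25), a_draws=np.full(50, 0.5))
        pred = predict_age_frequencies(res, max_age=15, n_colony=200)
        logs = np.log(pred.table["mean"])
        slope, intercept = np.polyfit(pred.table["age"], logs, 1)
        resid = logs - (slope * pred.table["age"] + intercept)
        assert np.max(np.abs(resid)) < 1e-10

    def test_count_below_one_threshold(self):
        # S=0.86 and 100 expected individuals at age 0: the mean count
        # first drops below 1 at ceil(ln(100)/0.15082) = 31
        a2 = -math.log(0.86)
        res = _constant_results(np.full(50, a2), a_draws=np.full(50, 1.0))
        pred = predict_age_frequencies(res, max_age=35, n_colony=100.0)
        assert pred.max_predicted_age == 31

    def test_relative_intervals_widen_with_age(self):
        rng = np.random.default_rng(3)
        res = _constant_results(
            rng.normal(0.2, 0.01, 2_000), a_draws=rng.normal(0.3, 0.005, 2_000)
        )
        pred = predict_age_frequencies(res, max_age=25, n_colony=100)
        log_width = np.log(pred.table["upper"]) - np.log(pred.table["lower"])
        beyond = log_width.values[4:]
        assert np.all(np.diff(beyond) > -1e-9)

    def test_max_age_must_cover_observations(self):
        res = _constant_results(np.full(10, 0.2))
        with pytest.raises(ValueError):
            predict_age_frequencies(res, max_age=1)
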