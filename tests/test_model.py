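"""Posterior density, initial conditions, MCMC fitting and DIC."""

import math

import numpy as np
import pytest
from scipy import stats

from silersurv import (
    CONSTANT,
    MATURATION,
    SENESCENCE,
    AgeFrequencyData,
    GrowthRate,
    MCMCConfig,
    PriorSpec,
    SilerModel,
    SilerParams,
    SilerResults,
    constant_scenario,
    fit_model,
    log_posterior,
    simulate_colony,
    split_rhat,
    survivorship,
)
from conftest import noise_free_constant_data

FAST = MCMCConfig(n_iterations=3000, n_warmup=1000, seed=0)


class TestLogPosterior:
    def test_zero_residuals_attain_gaussian_maximum(self):
        data = noise_free_constant_data(a2=0.3, max_age=10)
        p = SilerParams(a2=0.3, a=1.0, sigma=0.05)
        m = SilerModel(data, CONSTANT)
        n = len(data)
        assert m.loglike(p) == pytest.approx(
            -0.5 * n * math.log(2 * math.pi * 0.05**2), rel=1e-12
        )

    def test_amplitude_beyond_prior_bound_is_impossible(self):
        data = noise_free_constant_data()
        priors = PriorSpec(a_upper=1.0, sigma_upper=5.0)
        p = SilerParams(a2=0.3, a=1.5, sigma=0.1)
        assert log_posterior(p, CONSTANT, data, priors) == -np.inf

    def test_term_by_term_oracle(self):
        # three ages, senescence model: every prior and likelihood term
        # summed independently with scipy
        data = AgeFrequencyData(
            colony="t", ages=[0, 2, 5], frequencies=[0.5, 0.3, 0.1], n_total=10
        )
        priors = PriorSpec(a_upper=4.0, sigma_upper=2.0, normal_sd=0.1)
        p = SilerParams(a2=0.25, a3=0.02, b3=0.4, a=0.6, sigma=0.07)
        got = log_posterior(p, SENESCENCE, data, priors)
        x = np.array([0.0, 2.0, 5.0])
        mu = 0.6 * survivorship(p, SENESCENCE, x)
        expected = (
            stats.uniform.logpdf(0.6, 0, 4.0)
            + stats.norm.logpdf(0.25, 0, 0.1)
            + stats.norm.logpdf(0.02, 0, 0.1)
            + stats.norm.logpdf(0.4, 0, 0.1)
            + stats.uniform.logpdf(0.07, 0, 2.0)
            + stats.norm.logpdf(data.frequencies, mu, 0.07).sum()
        )
        assert got == pytest.approx(expected, abs=1e-10)


class TestInitialConditions:
    def test_zero_rss_grid_point_selected(self):
        data = noise_free_constant_data(a2=0.3)
        m = SilerModel(data, CONSTANT)
        best = m.initial_conditions({"a": [0.5, 1.0, 2.0], "a2": [0.1, 0.3, 0.6]})
        assert best.a2 == 0.3 and best.a == 1.0

    def test_singleton_grid(self):
        data = noise_free_constant_data()
        m = SilerModel(data, CONSTANT)
        best = m.initial_conditions({"a": [0.7], "a2": [0.2]})
        assert (best.a, best.a2) == (0.7, 0.2)

    def test_finer_grid_never_worse(self, constant_data):
        m = SilerModel(constant_data, CONSTANT)

        def rss(p):
            mu = p.a * survivorship(p, CONSTANT, constant_data.ages.astype(float))
            return float(((constant_data.frequencies - mu) ** 2).sum())

        coarse = {"a": [0.05, 0.2], "a2": [0.1, 0.4]}
        fine = {
            "a": np.linspace(0.05, 0.3, 11),
            "a2": np.linspace(0.05, 0.5, 19),
        }
        assert rss(m.initial_conditions(fine)) <= rss(m.initial_conditions(coarse))

    def test_missing_grid_entry_rejected(self):
        m = SilerModel(noise_free_constant_data(), CONSTANT)
        with pytest.raises(ValueError, match="grid"):
            m.initial_conditions({"a": [1.0]})


class TestFit:
    def test_seeded_fits_are_bit_identical(self, constant_data):
        r1 = fit_model(constant_data, CONSTANT, config=FAST)
        r2 = fit_model(constant_data, CONSTANT, config=FAST)
        np.testing.assert_array_equal(r1.chains, r2.chains)
        assert r1.dic == r2.dic

    def test_thinning_preserves_posterior_means(self, constant_data):
        import arviz as az

        cfg = MCMCConfig(n_iterations=10_000, seed=3)
        r1 = fit_model(constant_data, CONSTANT, config=cfg)
        r10 = fit_model(
            constant_data, CONSTANT, config=MCMCConfig(n_iterations=10_000, seed=3, thin=10)
        )
        for i, name in enumerate(r1.param_names):
            m1 = r1.draws_of(name).mean()
            m10 = r10.draws_of(name).mean()
            mcse = float(np.asarray(az.mcse(r1.chains[:, :, i])).ravel()[0]) + float(
                np.asarray(az.mcse(r10.chains[:, :, i])).ravel()[0]
            )
            assert abs(m1 - m10) < 2 * mcse

    def test_too_few_ages_rejected(self):
        data = AgeFrequencyData(colony="x", ages=[0, 1], frequencies=[0.6, 0.4], n_total=5)
        with pytest.raises(ValueError):
            SilerModel(data, CONSTANT)

    def test_warns_when_parameters_rival_ages(self):
        data = AgeFrequencyData(
            colony="x", ages=[0, 1, 2, 3], frequencies=[0.4, 0.3, 0.2, 0.1], n_total=10
        )
        from silersurv import SILER

        with pytest.warns(UserWarning, match="weakly identified"):
            SilerModel(data, SILER)

    def test_credible_interval_shrinks_with_sample_size(self):
        widths = []
        for n in (100, 1_000, 10_000):
            _, data = simulate_colony(constant_scenario(0.8, n, seed=11))
            res = fit_model(data, CONSTANT, config=MCMCConfig(seed=5))
            s = res.annual_survival()
            widths.append(s.upper - s.lower)
        assert widths[0] > widths[1] > widths[2]

    def test_growth_assumption_shifts_constant_hazard(self, constant_data):
        # fitting stationary data while assuming a 10% decline inflates
        # the recovered hazard by ~0.1 (the growth/mortality confound)
        r0 = fit_model(constant_data, CONSTANT, config=MCMCConfig(seed=7))
        r1 = fit_model(
            constant_data, CONSTANT, config=MCMCConfig(seed=7), growth=GrowthRate(-0.1)
        )
        shift = r1.posterior_mean["a2"] - r0.posterior_mean["a2"]
        assert shift == pytest.approx(0.1, abs=0.01)

    def test_summary_mentions_model_and_dic(self, constant_data):
        res = fit_model(constant_data, CONSTANT, config=FAST)
        text = res.summary()
        assert "CONSTANT" in text and "DIC" in text
        frame = res.summary_frame()
        assert list(frame.index) == list(res.param_names)
        ci = res.conf_int()
        assert np.all(ci["lower"].values <= ci["upper"].values)


class TestRhat:
    def test_identical_chains_converged(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal((1, 500, 2))
        chains = np.repeat(chain, 3, axis=0)
        assert np.all(split_rhat(chains) < 1.01)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((3, 400, 1)) * 0.1
        chains[0] += 5.0
        assert split_rhat(chains)[0] > 1.1

    def test_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(42)
        chains = rng.standard_normal((3, 1000, 2)) + rng.normal(
            0, 0.05, size=(3, 1, 2)
        )
        mine = split_rhat(chains)
        ref = az.rhat(az.convert_to_dataset(chains), method="split")["x"].values
        np.testing.assert_allclose(mine, ref, atol=0.01)


class TestDIC:
    @staticmethod
    def _three_point_model():
        data = AgeFrequencyData(
            colony="d", ages=[0, 1, 3], frequencies=[0.5, 0.35, 0.15], n_total=20
        )
        return SilerModel(data, CONSTANT)

    def test_degenerate_chain_has_zero_complexity(self):
        m = self._three_point_model()
        draws = np.tile([0.5, 0.3, 0.1], (200, 1))
        res = SilerResults.from_draws(m, draws)
        assert res.p_d == pytest.approx(0.0, abs=1e-9)
        assert res.dic == pytest.approx(res.mean_deviance, abs=1e-9)

    def test_hand_computed_four_draw_chain(self):
        m = self._three_point_model()
        draws = np.array(
            [
                [0.50, 0.30, 0.10],
                [0.52, 0.28, 0.12],
                [0.48, 0.33, 0.09],
                [0.51, 0.31, 0.11],
            ]
        )
        y = m.data.frequencies
        x = m.data.ages.astype(float)

        def dev(theta):
            a, a2, sigma = theta
            mu = a * np.exp(-a2 * x)
            return -2 * stats.norm.logpdf(y, mu, sigma).sum()

        dbar = np.mean([dev(t) for t in draws])
        dhat = dev(draws.mean(axis=0))
        res = SilerResults.from_draws(m, draws)
        assert res.dic == pytest.approx(dbar + (dbar - dhat), abs=1e-10)
        assert res.p_d == pytest.approx(dbar - dhat, abs=1e-10)

    def test_inactive_component_leaves_dic_unchanged(self):
        data = AgeFrequencyData(
            colony="d",
            ages=[0, 1, 2, 3, 5],
            frequencies=[0.4, 0.28, 0.17, 0.1, 0.05],
            n_total=50,
        )
        m_c = SilerModel(data, CONSTANT)
        m_m = SilerModel(data, MATURATION)
        rng = np.random.default_rng(0)
        base = np.column_stack(
            [
                0.4 + 0.01 * rng.standard_normal(100),
                0.3 + 0.01 * rng.standard_normal(100),
                0.05 + 0.001 * rng.standard_normal(100),
            ]
        )
        with_inactive = np.column_stack(
            [base[:, 0], np.zeros(100), np.full(100, 0.5), base[:, 1], base[:, 2]]
        )
        r_c = SilerResults.from_draws(m_c, base)
        r_m = SilerResults.from_draws(m_m, with_inactive)
        assert r_m.dic == pytest.approx(r_c.dic, abs=1e-10)
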