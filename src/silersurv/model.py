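"""Bayesian fitting of Siler-type survivorship models to age frequencies.

The observation model is the one used for tooth-cementum life-table
analysis: standardized observed frequencies ``y_i`` at integer ages
``x_i`` are treated as normally distributed about the expected frequency

    mu_i = a * lambda**(-x_i) * l(x_i),

with common residual standard deviation ``sigma``.  Priors are
uninformative: zero-mean normals (sd 100 by default) on the hazard
parameters and uniform priors on the amplitude ``a`` and on ``sigma``.
The normals on a1, a2, a3 are deliberately untruncated — on data without
a maturation or senescence signal their posteriors straddle zero, which
keeps the posterior-mean DIC plug-in well behaved; the rate parameters
b1, b3 are truncated at zero so each component keeps its identity
(declining juvenile hazard, rising senescent hazard).  Negative hazard
amplitudes are meaningful only as regression curvature, not as
survivorship; demographic conversions require non-negative hazards.

Sampling uses an adaptive random-walk Metropolis algorithm: the proposal
covariance is adapted (Haario-style, from the accumulated chain history,
with a Robbins-Monro tuned global scale) during burn-in only and frozen
afterwards, so the retained draws form a genuine Markov chain.  Three
independent chains are run by default and convergence is monitored with
the split-R-hat statistic.

Usage follows the Model/Results pattern::

    model = SilerModel(data, CONSTANT)
    res = model.fit(MCMCConfig(seed=1))
    res.summary()
    res.annual_survival()
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .core import (
    CONSTANT,
    GrowthRate,
    ModelSpec,
    SilerParams,
    expected_frequency,
)
from .preprocessing import AgeFrequencyData

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "SilerModel",
    "SilerResults",
    "log_posterior",
    "initial_conditions",
    "fit_model",
    "split_rhat",
]

_LOG_2PI = math.log(2.0 * math.pi)
_B_SMALL = 1e-8


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    a_upper, sigma_upper
        Upper bounds of the uniform priors on the amplitude ``a`` and the
        residual sd ``sigma``.  ``None`` means "resolve from the data":
        10x the maximum observed frequency and 10x the standard deviation
        of the observed frequencies, respectively.
    normal_sd
        Standard deviation of the zero-mean normal priors on the hazard
        parameters a1, b1, a2, a3, b3.  The default 0.1 corresponds to
        the BUGS idiom ``dnorm(0, 100)`` read as mean/precision
        (precision 100).  It is weakly informative on the per-year
        hazard scale, and it keeps the Gompertz rate parameters b1, b3
        confined to values resolvable from integer-age data — with a
        much flatter prior their posteriors spread over regions where
        exp(b * age) overflows any plug-in estimate and DIC degenerates.
        Pass a larger value for a flatter prior.
    """

    a_upper: Optional[float] = None
    sigma_upper: Optional[float] = None
    normal_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("a_upper", "sigma_upper", "normal_sd"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")

    def resolve(self, data: AgeFrequencyData) -> "PriorSpec":
        """Fill data-dependent defaults for the uniform prior bounds."""
        a_up = self.a_upper
        s_up = self.sigma_upper
        if a_up is None:
            a_up = 10.0 * float(np.max(data.frequencies))
        if s_up is None:
            sd = float(np.std(data.frequencies))
            s_up = 10.0 * (sd if sd > 0 else float(np.max(data.frequencies)))
        return PriorSpec(a_upper=a_up, sigma_upper=s_up, normal_sd=self.normal_sd)


@dataclass(frozen=True)
class MCMCConfig:
    """MCMC protocol: 3 chains of 10,000 iterations, 10% burn-in.

    ``n_warmup`` is an internal proposal-tuning phase run and discarded
    before the ``n_iterations`` recorded iterations begin (the same role
    as the adaptive phase BUGS samplers run before sampling); proposal
    adaptation continues through the burn-in fraction of the recorded
    iterations and is frozen afterwards.
    """

    n_chains: int = 3
    n_iterations: int = 10_000
    burnin_fraction: float = 0.1
    thin: int = 1
    seed: int = 0
    n_warmup: int = 2_000

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (needed for R-hat)")
        if not (0.0 <= self.burnin_fraction < 1.0):
            raise ValueError("burnin_fraction must lie in [0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_iterations < 10:
            raise ValueError("n_iterations too small")
        if self.n_warmup < 0:
            raise ValueError("n_warmup must be >= 0")


# ---------------------------------------------------------------------------
# parameter vector <-> SilerParams


def _param_names(model: ModelSpec) -> tuple:
    return ("a",) + model.hazard_param_names + ("sigma",)


def _vector_to_params(theta: np.ndarray, model: ModelSpec) -> SilerParams:
    kw = dict(zip(_param_names(model), theta))
    return SilerParams(
        a1=kw.get("a1", 0.0),
        b1=kw.get("b1", 0.0),
        a2=kw.get("a2", 0.0),
        a3=kw.get("a3", 0.0),
        b3=kw.get("b3", 0.0),
        a=kw["a"],
        sigma=kw["sigma"],
    )


def _params_to_vector(params: SilerParams, model: ModelSpec) -> np.ndarray:
    return np.array([getattr(params, n) for n in _param_names(model)], dtype=float)


def survivorship_from_vector(
    theta: np.ndarray, model: ModelSpec, x: np.ndarray
) -> np.ndarray:
    """l(x) from a raw posterior draw (tolerates negative hazard draws).

    Draws with negative a1/a2/a3 describe regression curvature rather
    than a proper survivorship; the returned values may then exceed 1.
    """
    x = np.asarray(x, dtype=float)
    mu = _make_mu_fn(model, x, 0.0)
    t = np.array(theta, dtype=float)
    t[0] = 1.0  # strip the amplitude
    return mu(t)


def _make_mu_fn(model: ModelSpec, x: np.ndarray, ln_lambda: float) -> Callable:
    """Compile a fast expected-frequency function of the parameter vector."""
    names = _param_names(model)
    idx = {n: i for i, n in enumerate(names)}
    has_m = "maturing" in model.components
    has_c = "constant" in model.components
    has_s = "senescing" in model.components
    tilt = -ln_lambda * x

    def mu(theta: np.ndarray) -> np.ndarray:
        h = tilt.copy()
        if has_m:
            a1, b1 = theta[idx["a1"]], theta[idx["b1"]]
            if b1 < _B_SMALL:
                h -= a1 * x
            else:
                h -= (a1 / b1) * (1.0 - np.exp(-b1 * x))
        if has_c:
            h -= theta[idx["a2"]] * x
        if has_s:
            a3, b3 = theta[idx["a3"]], theta[idx["b3"]]
            if b3 < _B_SMALL:
                h -= a3 * x
            else:
                h -= (a3 / b3) * (np.exp(b3 * x) - 1.0)
        return theta[0] * np.exp(h)

    return mu


# ---------------------------------------------------------------------------
# model


class SilerModel:
    """Siler-type survivorship model for one colony's age frequencies.

    Parameters
    ----------
    data : AgeFrequencyData
        Standardized observed frequencies per integer age.
    model : ModelSpec
        Which hazard components to include (one of the five candidates).
    priors : PriorSpec, optional
        Prior hyperparameters; data-dependent bounds resolved on entry.
    growth : GrowthRate, optional
        Assumed population growth; default stationary (ln lambda = 0).
    """

    def __init__(
        self,
        data: AgeFrequencyData,
        model: ModelSpec = CONSTANT,
        priors: PriorSpec = PriorSpec(),
        growth: GrowthRate = GrowthRate(),
    ) -> None:
        if len(data) < 3:
            raise ValueError("need at least 3 distinct ages to fit")
        self.data = data
        self.model = model
        self.priors = priors.resolve(data)
        self.growth = growth
        self.param_names = _param_names(model)
        self.n_params = len(self.param_names)
        if len(data) <= self.n_params:
            warnings.warn(
                f"only {len(data)} ages for {self.n_params} parameters; "
                "posterior will be weakly identified",
                stacklevel=2,
            )
        self._x = data.ages.astype(float)
        self._y = data.frequencies.astype(float)
        self._mu = _make_mu_fn(model, self._x, growth.ln_lambda)
        self._sigma_idx = self.n_params - 1
        self._b_indices = {
            n: i for i, n in enumerate(self.param_names) if n in ("b1", "b3")
        }

    # -- densities ----------------------------------------------------------

    def loglike(self, theta: np.ndarray | SilerParams) -> float:
        """Normal log-likelihood of the observed frequencies."""
        if isinstance(theta, SilerParams):
            theta = _params_to_vector(theta, self.model)
        sigma = theta[self._sigma_idx]
        if sigma <= 0:
            return -np.inf
        with np.errstate(over="ignore", invalid="ignore"):
            mu = self._mu(theta)
            if not np.all(np.isfinite(mu)):
                return -np.inf
            resid = self._y - mu
            rss = float(resid @ resid)
        if not np.isfinite(rss):
            return -np.inf
        n = resid.size
        with np.errstate(over="ignore"):
            return float(
                -0.5 * n * (_LOG_2PI + 2.0 * math.log(sigma))
                - 0.5 * rss / (sigma * sigma)
            )

    def logprior(self, theta: np.ndarray) -> float:
        """Log prior density; -inf outside the support.

        a ~ U(0, m_a); sigma ~ U(0, m_sigma); a1, a2, a3 ~ N(0, sd)
        untruncated; b1, b3 ~ N(0, sd) truncated at 0 (density kept as
        the plain normal pdf — the truncation constant is parameter-free
        and cancels everywhere it matters).
        """
        a = theta[0]
        sigma = theta[self._sigma_idx]
        if not (0.0 <= a <= self.priors.a_upper):
            return -np.inf
        if not (0.0 < sigma <= self.priors.sigma_upper):
            return -np.inf
        for name in ("b1", "b3"):
            if name in self._b_indices and theta[self._b_indices[name]] < 0:
                return -np.inf
        lp = -math.log(self.priors.a_upper) - math.log(self.priors.sigma_upper)
        sd = self.priors.normal_sd
        hz = theta[1 : self._sigma_idx]
        lp += float(
            -0.5 * hz.size * (_LOG_2PI + 2.0 * math.log(sd))
            - 0.5 * float(hz @ hz) / (sd * sd)
        )
        return lp

    def logpost(self, theta: np.ndarray) -> float:
        lp = self.logprior(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.loglike(theta)

    def _logpost_ll(self, theta: np.ndarray):
        """(log posterior, log likelihood) in one pass."""
        lp = self.logprior(theta)
        if not np.isfinite(lp):
            return -np.inf, -np.inf
        ll = self.loglike(theta)
        return lp + ll, ll

    # -- initial conditions -------------------------------------------------

    def default_grid(self) -> dict:
        """Coarse grid of plausible starting values, scaled to the data.

        The maturation and senescence amplitudes include negative
        values: the priors are untruncated, and on data without a real
        maturation or senescence signal the least-squares optimum can
        sit at a (mildly) negative amplitude; starting every chain in
        that global basin keeps the chains in agreement.
        """
        fmax = float(np.max(self._y))
        grid = {"a": fmax * np.array([0.5, 0.8, 1.0, 1.5, 2.0])}
        surv = np.array([0.4, 0.55, 0.65, 0.75, 0.86, 0.95])
        amp = np.array([-0.3, -0.1, -0.03, 0.0, 0.03, 0.1, 0.3, 0.8, 1.5])
        rate = np.array([0.03, 0.1, 0.3, 0.6, 1.0, 2.0])
        if "constant" in self.model.components:
            grid["a2"] = -np.log(surv)
        if "maturing" in self.model.components:
            grid["a1"] = amp
            grid["b1"] = rate
        if "senescing" in self.model.components:
            grid["a3"] = amp
            grid["b3"] = rate
        return grid

    def _grid_search(self, grid: Optional[Mapping] = None) -> np.ndarray:
        """Best-RSS grid point as a raw parameter vector (sigma = RMS)."""
        if grid is None:
            grid = self.default_grid()
        names = [n for n in self.param_names if n != "sigma"]
        missing = [n for n in names if n not in grid]
        if missing:
            raise ValueError(f"grid missing entries for parameters {missing}")
        cols = [np.atleast_1d(np.asarray(grid[n], dtype=float)) for n in names]
        mesh = np.meshgrid(*cols, indexing="ij")
        combos = np.stack([m.ravel() for m in mesh], axis=1)  # (N, k)
        if "b1" in names:
            combos = combos[combos[:, names.index("b1")] > 0]
        if "b3" in names:
            combos = combos[combos[:, names.index("b3")] > 0]
        if combos.shape[0] == 0:
            raise ValueError("no valid parameter combination in the grid")
        x = self._x
        col = {n: combos[:, i][:, None] for i, n in enumerate(names)}
        with np.errstate(over="ignore", invalid="ignore"):
            h = np.zeros((combos.shape[0], x.size))
            h -= self.growth.ln_lambda * x
            if "maturing" in self.model.components:
                h -= (col["a1"] / col["b1"]) * (1.0 - np.exp(-col["b1"] * x))
            if "constant" in self.model.components:
                h -= col["a2"] * x
            if "senescing" in self.model.components:
                h -= (col["a3"] / col["b3"]) * (np.exp(col["b3"] * x) - 1.0)
            mu = col["a"] * np.exp(h)
            rss = np.nansum((self._y - mu) ** 2, axis=1)
        rss = np.where(np.all(np.isfinite(mu), axis=1), rss, np.inf)
        best_idx = int(np.argmin(rss))
        if not np.isfinite(rss[best_idx]):
            raise ValueError("no valid parameter combination in the grid")
        best = np.append(combos[best_idx], 1.0)
        sigma0 = max(
            math.sqrt(rss[best_idx] / self._y.size), 1e-6 * float(np.max(self._y))
        )
        best[-1] = min(sigma0, 0.99 * self.priors.sigma_upper)
        best[0] = float(np.clip(best[0], 0.0, 0.99 * self.priors.a_upper))
        return best

    def initial_conditions(self, grid: Optional[Mapping] = None) -> SilerParams:
        """Least-squares grid search for starting values.

        Evaluates the residual sum of squares of the expected-frequency
        curve at every point of the (product) grid and returns the best,
        with ``sigma`` set to the corresponding RMS residual.  The
        returned :class:`SilerParams` is a valid survivorship parameter
        set, so any negative grid amplitudes in the best point are
        clipped to 0 here (the raw best point is still used internally
        to start the chains).
        """
        best = self._grid_search(grid)
        clipped = np.maximum(best, 0.0)
        return _vector_to_params(clipped, self.model)

    # -- sampling -----------------------------------------------------------

    def _jitter(self, theta0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Randomized per-chain start: tight jitter around the grid point."""
        scale = np.maximum(0.1 * np.abs(theta0), 1e-3)
        for _ in range(100):
            theta = theta0 + scale * rng.standard_normal(theta0.size)
            for i in self._b_indices.values():
                theta[i] = abs(theta[i])  # rates must stay positive
            theta[0] = abs(theta[0])
            theta[self._sigma_idx] = abs(theta[self._sigma_idx])
            if np.isfinite(self.logpost(theta)):
                return theta
        return theta0

    def _run_chain(
        self, theta0: np.ndarray, config: MCMCConfig, rng: np.random.Generator
    ):
        d = theta0.size
        n_warm = config.n_warmup
        n_iter = n_warm + config.n_iterations
        n_burn = n_warm + int(config.burnin_fraction * config.n_iterations)
        scale_step = np.maximum(0.1 * np.abs(theta0), 1e-4)
        chol = np.diag(scale_step)
        log_scale = math.log(2.38 / math.sqrt(d))
        target_acc = 0.3

        samples = np.empty((n_iter, d))
        loglik = np.empty(n_iter)
        theta = theta0.copy()
        lp, ll = self._logpost_ll(theta)
        if not np.isfinite(lp):
            raise ValueError("initial state has zero posterior density")

        # running moments for Haario covariance adaptation
        run_mean = theta.copy()
        run_cov = np.zeros((d, d))

        for i in range(n_iter):
            step = math.exp(log_scale) * (chol @ rng.standard_normal(d))
            prop = theta + step
            lp_prop, ll_prop = self._logpost_ll(prop)
            if np.isfinite(lp_prop):
                log_alpha = lp_prop - lp
                accept = log_alpha >= 0 or math.log(rng.random()) < log_alpha
                acc_prob = min(1.0, math.exp(min(log_alpha, 0.0)))
            else:
                accept = False
                acc_prob = 0.0
            if accept:
                theta = prop
                lp = lp_prop
                ll = ll_prop
            samples[i] = theta
            loglik[i] = ll

            if i < n_burn:
                # Robbins-Monro scale tuning toward the target acceptance
                log_scale += (acc_prob - target_acc) / math.sqrt(i + 1.0)
                delta = theta - run_mean
                run_mean += delta / (i + 2.0)
                run_cov += np.outer(delta, theta - run_mean)
                if i >= max(50, 2 * d) and (i + 1) % 50 == 0:
                    cov = run_cov / (i + 1.0) + 1e-10 * np.eye(d)
                    try:
                        chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
        return samples, loglik

    def fit(
        self,
        config: MCMCConfig = MCMCConfig(),
        start: Optional[SilerParams] = None,
        grid: Optional[Mapping] = None,
    ) -> "SilerResults":
        """Sample the posterior and return a results object.

        Runs ``config.n_chains`` independent adaptive-Metropolis chains
        from jittered least-squares starting values, discards burn-in,
        applies thinning, and computes summaries, split-R-hat and DIC.
        Identical configs (including seed) give identical results.
        """
        if start is None:
            theta0 = self._grid_search(grid)
        else:
            theta0 = _params_to_vector(start, self.model)

        seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
        chains = []
        logliks = []
        n_drop = config.n_warmup + int(config.burnin_fraction * config.n_iterations)
        for ss in seeds:
            rng = np.random.default_rng(ss)
            t0 = self._jitter(theta0, rng)
            samples, ll = self._run_chain(t0, config, rng)
            chains.append(samples[n_drop :: config.thin])
            logliks.append(ll[n_drop :: config.thin])
        return SilerResults(
            model_spec=self.model,
            data=self.data,
            growth=self.growth,
            priors=self.priors,
            config=config,
            param_names=self.param_names,
            chains=np.asarray(chains),
            loglik_chains=np.asarray(logliks),
            siler_model=self,
        )


# ---------------------------------------------------------------------------
# diagnostics


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat (Gelman-Rubin) per parameter.

    ``chains`` has shape (n_chains, n_draws, n_params).  Each chain is
    split in half, and the classic potential-scale-reduction factor
    sqrt(((n-1)/n * W + B/n) / W) is computed over the split halves.
    """
    m, n, d = chains.shape
    half = n // 2
    split = chains[:, : 2 * half].reshape(2 * m, half, d)
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean(axis=0)
    b = half * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (half - 1) / half * w + b / half
        rhat = np.sqrt(var_plus / w)
    # a parameter stuck at a constant has W == 0; treat as converged
    return np.where(w > 0, rhat, 1.0)


# ---------------------------------------------------------------------------
# results


@dataclass
class SilerResults:
    """Posterior draws and summaries from :meth:`SilerModel.fit`.

    Exposes posterior means, equal-tailed 95% credible intervals,
    split-R-hat diagnostics, DIC, and demographic post-processing
    (annual survival, life expectancy, predicted age frequencies).
    """

    model_spec: ModelSpec
    data: AgeFrequencyData
    growth: GrowthRate
    priors: PriorSpec
    config: Optional[MCMCConfig]
    param_names: tuple
    chains: np.ndarray  # (n_chains, n_draws, n_params)
    loglik_chains: Optional[np.ndarray] = None
    siler_model: Optional[SilerModel] = None

    def __post_init__(self) -> None:
        self.chains = np.asarray(self.chains, dtype=float)
        if self.chains.ndim != 3:
            raise ValueError("chains must have shape (n_chains, n_draws, n_params)")
        if self.siler_model is None:
            self.siler_model = SilerModel(
                self.data, self.model_spec, self.priors, self.growth
            )
        if self.loglik_chains is None:
            m = self.siler_model
            self.loglik_chains = np.apply_along_axis(m.loglike, 2, self.chains)

    @classmethod
    def from_draws(
        cls,
        model: SilerModel,
        draws: np.ndarray,
        config: Optional[MCMCConfig] = None,
    ) -> "SilerResults":
        """Build a results object from externally supplied draws.

        ``draws`` may be (n_draws, n_params) — treated as two identical
        chains for diagnostics — or (n_chains, n_draws, n_params).
        """
        draws = np.asarray(draws, dtype=float)
        if draws.ndim == 2:
            draws = np.stack([draws, draws])
        return cls(
            model_spec=model.model,
            data=model.data,
            growth=model.growth,
            priors=model.priors,
            config=config,
            param_names=model.param_names,
            chains=draws,
            siler_model=model,
        )

    # -- basic posterior access --------------------------------------------

    @property
    def draws(self) -> np.ndarray:
        """Pooled post-burn-in draws, shape (n_total_draws, n_params)."""
        return self.chains.reshape(-1, self.chains.shape[-1])

    def draws_of(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    @property
    def posterior_mean(self) -> dict:
        means = self.draws.mean(axis=0)
        return dict(zip(self.param_names, means))

    def conf_int(self, alpha: float = 0.05):
        """Equal-tailed credible intervals per parameter."""
        import pandas as pd

        lo, hi = np.percentile(
            self.draws, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0
        )
        return pd.DataFrame({"lower": lo, "upper": hi}, index=list(self.param_names))

    @property
    def rhat(self) -> dict:
        return dict(zip(self.param_names, split_rhat(self.chains)))

    @property
    def converged(self) -> bool:
        return bool(all(r <= 1.1 for r in self.rhat.values()))

    def to_params(self) -> SilerParams:
        """Posterior-mean point estimate as a SilerParams.

        Small negative posterior means of hazard amplitudes (possible
        because the a1/a2/a3 priors are untruncated) are clipped to 0:
        a proper survivorship requires non-negative hazards.
        """
        mean = np.maximum(self.draws.mean(axis=0), 0.0)
        return _vector_to_params(mean, self.model_spec)

    # -- DIC ----------------------------------------------------------------

    @property
    def mean_deviance(self) -> float:
        return float(np.mean(-2.0 * self.loglik_chains))

    @property
    def deviance_at_mean(self) -> float:
        return -2.0 * self.siler_model.loglike(self.draws.mean(axis=0))

    @property
    def p_d(self) -> float:
        return self.mean_deviance - self.deviance_at_mean

    @property
    def dic(self) -> float:
        return self.mean_deviance + self.p_d

    # -- demographic post-processing ----------------------------------------

    def annual_survival(self, age: Optional[float] = None):
        from .demography import posterior_annual_survival

        return posterior_annual_survival(self, age=age)

    def life_expectancy(self):
        from .demography import life_expectancy, posterior_annual_survival

        s = posterior_annual_survival(self)
        return life_expectancy(s.mean)

    def predict_age_frequencies(self, max_age: int, n_colony: float = 1.0):
        from .demography import predict_age_frequencies

        return predict_age_frequencies(self, max_age=max_age, n_colony=n_colony)

    # -- reporting ----------------------------------------------------------

    def summary_frame(self):
        import pandas as pd

        draws = self.draws
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "mean": draws.mean(axis=0),
                "sd": draws.std(axis=0, ddof=1),
                "2.5%": lo,
                "97.5%": hi,
                "rhat": [self.rhat[n] for n in self.param_names],
            },
            index=list(self.param_names),
        )

    def summary(self) -> str:
        lines = [
            f"Siler survivorship fit: model {self.model_spec.name}, "
            f"colony {self.data.colony}",
            f"ages: {len(self.data)}, draws: {self.draws.shape[0]} "
            f"({self.chains.shape[0]} chains), ln(lambda) = {self.growth.ln_lambda:g}",
            f"DIC = {self.dic:.2f}  (Dbar = {self.mean_deviance:.2f}, "
            f"pD = {self.p_d:.2f})",
            f"converged (all split-Rhat <= 1.1): {self.converged}",
            "",
            self.summary_frame().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers mirroring the procedural interface


def log_posterior(
    params: SilerParams,
    model: ModelSpec,
    data: AgeFrequencyData,
    priors: PriorSpec = PriorSpec(),
    growth: GrowthRate = GrowthRate(),
) -> float:
    """Log posterior density of ``params`` given the data."""
    m = SilerModel(data, model, priors, growth)
    return m.logpost(_params_to_vector(params, model))


def initial_conditions(
    data: AgeFrequencyData,
    model: ModelSpec,
    grid: Optional[Mapping] = None,
    priors: PriorSpec = PriorSpec(),
    growth: GrowthRate = GrowthRate(),
) -> SilerParams:
    """Grid-search starting values (least-squares best grid point)."""
    return SilerModel(data, model, priors, growth).initial_conditions(grid)


def fit_model(
    data: AgeFrequencyData,
    model: ModelSpec,
    priors: PriorSpec = PriorSpec(),
    config: MCMCConfig = MCMCConfig(),
    growth: GrowthRate = GrowthRate(),
) -> SilerResults:
    """Fit one candidate model; see :meth:`SilerModel.fit`."""
    return SilerModel(data, model, priors, growth).fit(config)
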