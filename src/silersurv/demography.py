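"""Demographic summaries derived from fitted survivorship models.

Age-specific survival is S_x = l(x+1)/l(x); under the constant-risk
model the annual survival probability is S = exp(-a2) and mean life
expectancy is -1/ln(S).  Predicted age frequencies at colony scale are
obtained per posterior draw from the expected-frequency curve, and the
oldest plausible age is summarized as the first age at which the mean
expected count drops below one individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import GrowthRate, ModelSpec, SilerParams, expected_frequency, survivorship
from .model import SilerResults, _make_mu_fn

__all__ = [
    "age_specific_survival",
    "life_expectancy",
    "posterior_annual_survival",
    "predict_age_frequencies",
    "SurvivalSummary",
    "AgeFrequencyPrediction",
]


def age_specific_survival(params: SilerParams, model: ModelSpec, x) -> float | np.ndarray:
    """Probability S_x = l(x+1)/l(x) of surviving one more year at age x."""
    xv = np.asarray(x, dtype=float)
    out = np.asarray(survivorship(params, model, xv + 1.0)) / np.asarray(
        survivorship(params, model, xv)
    )
    return float(out) if out.ndim == 0 else out


def life_expectancy(s: float) -> float:
    """Mean life expectancy -1/ln(S) in years, for annual survival S."""
    if not (0.0 < s < 1.0):
        raise ValueError(f"annual survival must lie in (0, 1), got {s!r}")
    return -1.0 / math.log(s)


@dataclass(frozen=True)
class SurvivalSummary:
    """Posterior mean and equal-tailed 95% credible interval for S."""

    mean: float
    lower: float
    upper: float

    def __iter__(self):
        return iter((self.mean, self.lower, self.upper))


def posterior_annual_survival(
    fit: SilerResults, age: Optional[float] = None
) -> SurvivalSummary:
    """Posterior annual survival probability.

    For the constant-risk model this is S = exp(-a2) per draw.  For any
    other model an evaluation ``age`` must be given, and the per-draw
    age-specific survival S_age = l(age+1)/l(age) is summarized instead.
    """
    if age is None:
        if fit.model_spec.components != frozenset({"constant"}):
            raise ValueError(
                "annual survival without an age argument is defined only for "
                "the constant-risk model; pass age=x for S_x"
            )
        s_draws = np.exp(-fit.draws_of("a2"))
    else:
        if age < 0:
            raise ValueError("age must be >= 0")
        from .model import survivorship_from_vector

        xs = np.array([age, age + 1.0])
        lx = np.array(
            [survivorship_from_vector(theta, fit.model_spec, xs) for theta in fit.draws]
        )
        s_draws = lx[:, 1] / lx[:, 0]
    lo, hi = np.percentile(s_draws, [2.5, 97.5])
    return SurvivalSummary(mean=float(s_draws.mean()), lower=float(lo), upper=float(hi))


@dataclass(frozen=True)
class AgeFrequencyPrediction:
    """Predicted per-age expected counts with 95% credible intervals."""

    table: pd.DataFrame  # columns age, mean, lower, upper
    max_predicted_age: Optional[int]  # first age with mean expected count < 1
    n_colony: float


def predict_age_frequencies(
    fit: SilerResults, max_age: int, n_colony: float = 1.0
) -> AgeFrequencyPrediction:
    """Predicted age distribution at colony scale.

    For each posterior draw the expected frequency (in the fitted
    proportion units) is evaluated at integer ages 0..max_age and scaled
    by ``n_colony``; the per-age mean and equal-tailed 95% interval are
    reported.  ``max_predicted_age`` is the smallest age at which the
    mean expected count falls below one individual (searching beyond
    ``max_age`` if needed), i.e. the oldest age at which the model still
    predicts at least one living individual in a colony of this size.
    """
    if max_age < int(fit.data.ages.max()):
        raise ValueError("max_age must cover the oldest observed age")
    search_age = max(int(max_age), 400)
    ages = np.arange(search_age + 1, dtype=float)
    mu_fn = _make_mu_fn(fit.model_spec, ages, fit.growth.ln_lambda)
    counts = np.array([mu_fn(theta) for theta in fit.draws]) * n_colony
    mean = counts.mean(axis=0)
    below = np.nonzero(mean < 1.0)[0]
    max_pred = int(below[0]) if below.size else None

    keep = np.arange(int(max_age) + 1)
    lo, hi = np.percentile(counts[:, keep], [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {"age": keep, "mean": mean[keep], "lower": lo, "upper": hi}
    )
    return AgeFrequencyPrediction(table=table, max_predicted_age=max_pred, n_colony=n_colony)
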