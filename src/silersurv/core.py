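"""Closed-form Siler competing-hazard survivorship mathematics.

The Siler model describes mammalian mortality as the sum of three
competing hazards acting simultaneously: a declining Gompertz hazard for
juvenile maturation, a constant baseline hazard, and a rising Gompertz
hazard for senescence,

    mu(x) = a1 * exp(-b1 * x) + a2 + a3 * exp(b3 * x).

Survivorship to age ``x`` is the product of the component survivorships

    l1(x) = exp(-(a1/b1) * (1 - exp(-b1 * x)))   (maturation)
    l2(x) = exp(-a2 * x)                         (constant risk)
    l3(x) = exp((a3/b3) * (1 - exp(b3 * x)))     (senescence)

and the five candidate models used for age-at-capture life-table analysis
keep different subsets of the three components.  Under a population
growing at rate lambda per year the stable age distribution is
proportional to ``lambda**(-x) * l(x)``; scaled by an amplitude ``a`` this
is the expected age frequency that the observation model fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "SilerParams",
    "ModelSpec",
    "GrowthRate",
    "CONSTANT",
    "MATURATION",
    "SENESCENCE",
    "MATURATION_SENESCENCE",
    "SILER",
    "ALL_MODELS",
    "survivorship",
    "hazard",
    "expected_frequency",
]

# below this the Gompertz exponent is replaced by its b -> 0 limit
_B_SMALL = 1e-8

_COMPONENTS = frozenset({"maturing", "constant", "senescing"})


@dataclass(frozen=True)
class SilerParams:
    """Hazard parameters of the (up to) five-parameter Siler model.

    Parameters
    ----------
    a1 : float
        Initial maturation hazard at age 0 (per year).
    b1 : float
        Exponential decay rate of the maturation hazard (per year).
    a2 : float
        Age-independent baseline hazard (per year).
    a3 : float
        Initial senescence hazard at age 0 (per year).
    b3 : float
        Exponential growth rate of the senescence hazard (per year).
    a : float
        Amplitude scaling the expected age frequency; same units as the
        observed frequencies (proportion or count).
    sigma : float
        Residual standard deviation of observed frequencies about the
        expected frequency curve (observation noise).
    """

    a1: float = 0.0
    b1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    b3: float = 0.0
    a: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "a2", "a3", "b3", "a", "sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.a1 > 0 and self.b1 <= 0:
            raise ValueError("b1 must be > 0 when a1 > 0 (a1/b1 must be finite)")
        if self.a3 > 0 and self.b3 <= 0:
            raise ValueError("b3 must be > 0 when a3 > 0 (a3/b3 must be finite)")

    def replace(self, **changes: float) -> "SilerParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class ModelSpec:
    """One of the five candidate survivorship models.

    ``components`` is the subset of hazard elements the model keeps:
    ``maturing`` (a1, b1), ``constant`` (a2) and ``senescing`` (a3, b3).
    """

    name: str
    components: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("a model must include at least one hazard component")
        unknown = set(self.components) - _COMPONENTS
        if unknown:
            raise ValueError(f"unknown hazard components: {sorted(unknown)}")

    @property
    def hazard_param_names(self) -> tuple:
        """Active hazard parameters, in canonical order."""
        names: list = []
        if "maturing" in self.components:
            names += ["a1", "b1"]
        if "constant" in self.components:
            names += ["a2"]
        if "senescing" in self.components:
            names += ["a3", "b3"]
        return tuple(names)

    @property
    def n_hazard_params(self) -> int:
        return len(self.hazard_param_names)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


CONSTANT = ModelSpec("CONSTANT", frozenset({"constant"}))
MATURATION = ModelSpec("MATURATION", frozenset({"maturing", "constant"}))
SENESCENCE = ModelSpec("SENESCENCE", frozenset({"constant", "senescing"}))
MATURATION_SENESCENCE = ModelSpec(
    "MATURATION_SENESCENCE", frozenset({"maturing", "senescing"})
)
SILER = ModelSpec("SILER", frozenset({"maturing", "constant", "senescing"}))

ALL_MODELS = (CONSTANT, MATURATION, SENESCENCE, MATURATION_SENESCENCE, SILER)


@dataclass(frozen=True)
class GrowthRate:
    """Log of the annual population growth rate lambda.

    ``ln_lambda = 0`` is a stationary population; ``ln_lambda = -0.1``
    corresponds to a ~10% annual decline.
    """

    ln_lambda: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.ln_lambda):
            raise ValueError("ln_lambda must be finite")


def _check_age(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("age x must be finite and >= 0")
    return x


def _cum_hazard(params: SilerParams, model: ModelSpec, x: np.ndarray) -> np.ndarray:
    """Integrated hazard H(x) over the included components."""
    h = np.zeros_like(x)
    if "maturing" in model.components and params.a1 > 0:
        if params.b1 < _B_SMALL:
            h = h + params.a1 * x
        else:
            h = h + (params.a1 / params.b1) * (1.0 - np.exp(-params.b1 * x))
    if "constant" in model.components:
        h = h + params.a2 * x
    if "senescing" in model.components and params.a3 > 0:
        if params.b3 < _B_SMALL:
            h = h + params.a3 * x
        else:
            h = h + (params.a3 / params.b3) * (np.exp(params.b3 * x) - 1.0)
    return h


def survivorship(params: SilerParams, model: ModelSpec, x) -> np.ndarray | float:
    """Probability l(x) of surviving from birth to age ``x``.

    Product of the model's included component survivorships; l(0) = 1 and
    l is non-increasing in age.  Accepts scalar or array ages.
    """
    xv = _check_age(x)
    out = np.exp(-_cum_hazard(params, model, xv))
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def hazard(params: SilerParams, model: ModelSpec, x) -> np.ndarray | float:
    """Instantaneous mortality rate mu(x) = -d ln l(x) / dx (per year)."""
    xv = _check_age(x)
    mu = np.zeros_like(xv)
    if "maturing" in model.components:
        mu = mu + params.a1 * np.exp(-params.b1 * xv)
    if "constant" in model.components:
        mu = mu + params.a2
    if "senescing" in model.components:
        mu = mu + params.a3 * np.exp(params.b3 * xv)
    return float(mu) if np.isscalar(x) or np.ndim(x) == 0 else mu


def expected_frequency(
    params: SilerParams,
    model: ModelSpec,
    x,
    growth: GrowthRate = GrowthRate(),
) -> np.ndarray | float:
    """Expected age frequency a * lambda**(-x) * l(x).

    This is the stable-age-distribution shape under growth rate lambda,
    scaled by the amplitude ``a``; with a stationary population
    (``ln_lambda = 0``) and ``a = 1`` it reduces to the survivorship.
    """
    xv = _check_age(x)
    out = params.a * np.exp(-growth.ln_lambda * xv - _cum_hazard(params, model, xv))
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out
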