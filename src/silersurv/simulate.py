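"""Synthetic colony generator with the structure the analysis assumes.

Individuals are sampled from the stable age distribution implied by a
chosen survivorship model and population growth rate,
p(x) proportional to lambda**(-x) * l(x) over integer ages.  A
configurable fraction of captures are unaged 0-year juveniles (the
capture bias seen at the Bioko roost, where pups are netted but never
tooth-aged), sexes are Bernoulli draws, and an optional Gaussian
perturbation of the standardized frequencies exercises the normal-error
observation model explicitly (multinomial sampling noise is already
present, so ``noise_sd`` defaults to 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .core import GrowthRate, ModelSpec, SilerParams, survivorship
from .preprocessing import AgeFrequencyData, IndividualRecord, StandardizationSpec, standardize

__all__ = ["ColonyScenario", "stable_age_distribution", "simulate_colony", "constant_scenario"]

_TAIL_MASS = 1e-6
_MAX_AGE_CAP = 10_000


@dataclass(frozen=True)
class ColonyScenario:
    """Generating conditions for one synthetic colony.

    Defaults describe a typical study colony: a stationary population,
    every capture tooth-aged (no 0-class capture bias), an even sex
    ratio, and no extra observation noise beyond multinomial sampling.
    """

    true_params: SilerParams
    model: ModelSpec
    n_captures: int
    colony: str = "synthetic"
    ln_lambda: float = 0.0
    unaged_juvenile_proportion: float = 0.0
    proportion_male: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_captures <= 0:
            raise ValueError("n_captures must be > 0")
        for name in ("unaged_juvenile_proportion", "proportion_male"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def constant_scenario(
    annual_survival: float,
    n_captures: int,
    seed: int = 0,
    colony: str = "synthetic",
    **kwargs,
) -> ColonyScenario:
    """Constant-risk scenario parameterized directly by annual survival S."""
    from .core import CONSTANT

    if not (0.0 < annual_survival < 1.0):
        raise ValueError("annual_survival must lie in (0, 1)")
    params = SilerParams(a2=-np.log(annual_survival), a=1.0, sigma=1.0)
    return ColonyScenario(
        true_params=params,
        model=CONSTANT,
        n_captures=n_captures,
        seed=seed,
        colony=colony,
        **kwargs,
    )


def stable_age_distribution(
    params: SilerParams,
    model: ModelSpec,
    ln_lambda: float = 0.0,
    max_age: Optional[int] = None,
) -> np.ndarray:
    """Per-integer-age probabilities p(x) proportional to lambda**(-x) l(x).

    When ``max_age`` is None the support is extended until the
    remaining tail mass is below 1e-6.  Raises if the weights do not
    decay (population growth outpacing mortality truncation).
    """
    growth = GrowthRate(ln_lambda)

    def weights(upper: int) -> np.ndarray:
        x = np.arange(upper + 1, dtype=float)
        with np.errstate(over="ignore", invalid="ignore"):
            return np.exp(-ln_lambda * x) * survivorship(params, model, x)

    if max_age is not None:
        w = weights(int(max_age))
    else:
        upper = 64
        while True:
            w = weights(upper)
            if w[-1] < _TAIL_MASS * w.sum():
                break
            upper *= 2
            if upper > _MAX_AGE_CAP:
                raise ValueError(
                    "stable age distribution is not normalizable: the growth "
                    "tilt lambda**(-x) outpaces mortality; use a more negative "
                    "hazard or less negative ln_lambda, or pass max_age "
                    "explicitly to truncate"
                )
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("stable age distribution has no finite mass")
    return w / total


def simulate_colony(
    scenario: ColonyScenario,
) -> Tuple[list, AgeFrequencyData]:
    """Simulate one colony's capture records and standardized frequencies.

    Deterministically, ``floor(unaged_juvenile_proportion * n_captures)``
    captures are unaged 0-year juveniles; the remainder receive integer
    tooth-cementum ages drawn from the stable age distribution
    (conditioned on age >= 1 when the capture bias is active).  The
    records are then standardized exactly as field data would be, with
    the 0-class forced to the realized unaged-capture proportion; an
    optional Gaussian perturbation (sd ``noise_sd``, truncated at 0) is
    applied to the standardized frequencies afterwards.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_captures
    n_unaged = int(np.floor(scenario.unaged_juvenile_proportion * n))
    n_aged = n - n_unaged
    if n_aged == 0:
        raise ValueError("scenario leaves no tooth-aged individuals")

    p = stable_age_distribution(scenario.true_params, scenario.model, scenario.ln_lambda)
    ages_support = np.arange(p.size)
    if n_unaged > 0:
        cond = p.copy()
        cond[0] = 0.0
        cond /= cond.sum()
    else:
        cond = p
    ages = rng.choice(ages_support, size=n_aged, p=cond)
    sexes = np.where(rng.random(n) < scenario.proportion_male, "M", "F")

    records = [
        IndividualRecord(
            colony=scenario.colony, age_years=None, sex=sexes[i], certainty="none"
        )
        for i in range(n_unaged)
    ]
    records += [
        IndividualRecord(
            colony=scenario.colony,
            age_years=int(age),
            sex=sexes[n_unaged + i],
            certainty="A",
        )
        for i, age in enumerate(ages)
    ]

    spec = StandardizationSpec(
        mode="proportion",
        zero_class_proportion=(n_unaged / n) if n_unaged > 0 else None,
    )
    data = standardize(records, spec)

    if scenario.noise_sd > 0:
        noisy = data.frequencies + scenario.noise_sd * rng.standard_normal(len(data))
        data = AgeFrequencyData(
            colony=data.colony,
            ages=data.ages,
            frequencies=np.maximum(noisy, 0.0),
            n_total=data.n_total,
        )
    return records, data
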