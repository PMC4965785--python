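"""Regression of colony survival estimates on colony-level covariates.

Colony-constant survival estimates are regressed on covariates such as
estimated population size, subjective hunting-pressure rank (0-1) and
the proportion of males among captures, by ordinary least squares with
an F-test on the slope (df 1, n-2).  Optionally the regression can be
weighted by the precision of each survival estimate (inverse squared
credible-interval width); unweighted is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ColonyCovariates", "OLSSummary", "ols_fit", "regress_survival"]


@dataclass(frozen=True)
class ColonyCovariates:
    """Colony-level covariates for the survival regression."""

    colony: str
    population_size: float
    hunting_rank: float
    proportion_male: float
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        if self.population_size <= 0:
            raise ValueError("population_size must be > 0")
        for name in ("hunting_rank", "proportion_male"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class OLSSummary:
    """Simple-linear-regression estimates with overall F-test."""

    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    r_squared: float
    n: int


def ols_fit(x, y, weights: Optional[Sequence[float]] = None) -> OLSSummary:
    """Simple linear regression of y on x with an F-test.

    F has (1, n-2) degrees of freedom.  A constant response gives slope
    0, F = 0, p = 1 (no explainable variance).  Weighted least squares
    is used when ``weights`` is given.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate covariate: x is constant")

    design = sm.add_constant(x)
    if weights is None:
        res = sm.OLS(y, design).fit()
    else:
        res = sm.WLS(y, design, weights=np.asarray(weights, dtype=float)).fit()

    f = float(res.fvalue)
    p = float(res.f_pvalue)
    r2 = float(res.rsquared)
    if res.ess <= max(1e-30, 1e-15 * (res.ess + res.ssr)):  # flat response
        f, p, r2 = 0.0, 1.0, 0.0
    return OLSSummary(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        f_statistic=f,
        p_value=p,
        r_squared=r2,
        n=int(x.size),
    )


def regress_survival(
    covariates: Sequence[ColonyCovariates],
    survival: dict,
    x_field: str = "proportion_male",
    weights: Optional[dict] = None,
) -> OLSSummary:
    """Regress per-colony survival estimates on one covariate.

    ``survival`` maps colony label to the (posterior mean) annual
    survival estimate; ``weights`` optionally maps colony label to a
    regression weight.  Colonies missing from ``survival`` are dropped.
    """
    rows = [(c, getattr(c, x_field)) for c in covariates if c.colony in survival]
    if not rows:
        raise ValueError("no colonies in common between covariates and survival")
    x = np.array([v for _, v in rows])
    y = np.array([survival[c.colony] for c, _ in rows])
    w = None
    if weights is not None:
        w = np.array([weights[c.colony] for c, _ in rows])
    return ols_fit(x, y, weights=w)
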