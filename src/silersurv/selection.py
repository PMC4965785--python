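"""DIC-based comparison of the five candidate survivorship models.

DIC = Dbar + pD with pD = Dbar - D(theta_bar), where the deviance is
-2x the (likelihood-only) log likelihood and theta_bar is the posterior
mean of the active parameters.  Differences above two DIC units are
treated as meaningful; within two units the most parsimonious model
(fewest active hazard parameters) is retained as the working model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import ModelSpec
from .model import SilerResults

__all__ = ["compute_dic", "select_model", "ModelComparison", "DIC_SUPPORT_THRESHOLD"]

DIC_SUPPORT_THRESHOLD = 2.0


def compute_dic(fit: SilerResults) -> float:
    """Deviance information criterion of a fitted model."""
    return fit.dic


@dataclass(frozen=True)
class ModelComparison:
    """Ranked DIC table plus the selection decision.

    ``best`` is the lowest-DIC model; it is ``supported`` only when it
    beats every competitor by more than two DIC units.  ``selected`` is
    the working model: the best when supported, otherwise the model with
    the fewest hazard parameters among those within two units of the
    best (ties broken by lower DIC).
    """

    table: pd.DataFrame
    best: str
    supported: bool
    selected: str


def _as_entries(fits: Sequence) -> list:
    """Normalize input to (name, n_hazard_params, dic, fit_or_None)."""
    entries = []
    for item in fits:
        if isinstance(item, SilerResults):
            entries.append(
                (item.model_spec.name, item.model_spec.n_hazard_params, item.dic, item)
            )
        else:
            spec, dic = item
            if isinstance(spec, ModelSpec):
                entries.append((spec.name, spec.n_hazard_params, float(dic), None))
            else:
                entries.append((str(spec), np.nan, float(dic), None))
    return entries


def select_model(fits: Sequence) -> ModelComparison:
    """Rank candidate models by DIC and pick the working model.

    ``fits`` is a list of :class:`SilerResults` (which must share the
    same dataset), or of ``(ModelSpec | name, dic)`` pairs for pure rule
    application to externally supplied DIC values.  When parameter
    counts are unavailable, parsimony falls back to the lowest DIC
    within the two-unit band.
    """
    entries = _as_entries(fits)
    if len(entries) < 2:
        raise ValueError("need at least two fitted models to compare")
    names = [e[0] for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate models in comparison")

    results = [e[3] for e in entries if e[3] is not None]
    for other in results[1:]:
        same = (
            other.data.colony == results[0].data.colony
            and np.array_equal(other.data.ages, results[0].data.ages)
            and np.allclose(other.data.frequencies, results[0].data.frequencies)
        )
        if not same:
            raise ValueError("fits were made on different datasets")

    entries.sort(key=lambda e: e[2])
    best_name, _, best_dic, _ = entries[0]
    supported = all(dic - best_dic > DIC_SUPPORT_THRESHOLD for _, _, dic, _ in entries[1:])
    if supported:
        selected = best_name
    else:
        band = [e for e in entries if e[2] - best_dic <= DIC_SUPPORT_THRESHOLD]
        if all(np.isfinite(e[1]) for e in band):
            band.sort(key=lambda e: (e[1], e[2]))
        selected = band[0][0]

    table = pd.DataFrame(
        {
            "model": [e[0] for e in entries],
            "n_hazard_params": [e[1] for e in entries],
            "dic": [e[2] for e in entries],
            "delta_dic": [e[2] - best_dic for e in entries],
        }
    )
    return ModelComparison(table=table, best=best_name, supported=supported, selected=selected)
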