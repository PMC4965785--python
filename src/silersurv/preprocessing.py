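"""Reading, filtering and standardizing colony age data.

Individuals are aged in integer years from tooth-cementum annuli, each
age assigned a certainty code (A highest, B supported within roughly a
year, C unusable).  Some captures — very young pups — are never
tooth-aged at all; they form an "unaged juvenile" 0-year class whose
observed proportion among all captures can be used to correct the
tooth-aged age structure for this capture bias (as for the Bioko colony,
where 84 of 105 captures were unaged pups).

Standardization converts records into per-age observed frequencies: the
proportions of individuals in each age class, with the 0-class forced to
the observed capture proportion when a bias correction applies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IndividualRecord",
    "AgeFrequencyData",
    "StandardizationSpec",
    "filter_records",
    "standardize",
    "read_colony_csv",
    "write_age_frequencies",
]

UNAGED = "unaged_juvenile"

_SEXES = {"M", "F", "unknown"}
_CERTAINTIES = {"A", "B", "C", "none"}


@dataclass(frozen=True)
class IndividualRecord:
    """A single captured individual.

    ``age_years`` is the tooth-cementum age in whole years, or ``None``
    for an unaged juvenile (a pup captured but never tooth-aged).
    """

    colony: str
    age_years: Optional[int]
    sex: str = "unknown"
    certainty: str = "none"
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_years is not None:
            if int(self.age_years) != self.age_years or self.age_years < 0:
                raise ValueError(f"age_years must be a non-negative integer or None, got {self.age_years!r}")
            object.__setattr__(self, "age_years", int(self.age_years))
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {sorted(_SEXES)}, got {self.sex!r}")
        if self.certainty not in _CERTAINTIES:
            raise ValueError(f"certainty must be one of {sorted(_CERTAINTIES)}, got {self.certainty!r}")

    @property
    def is_aged(self) -> bool:
        return self.age_years is not None


@dataclass(frozen=True)
class AgeFrequencyData:
    """Standardized per-age observed frequencies for one colony."""

    colony: str
    ages: np.ndarray
    frequencies: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        freqs = np.asarray(self.frequencies, dtype=float)
        if ages.ndim != 1 or freqs.shape != ages.shape:
            raise ValueError("ages and frequencies must be 1-d arrays of equal length")
        if ages.size == 0:
            raise ValueError("age-frequency data must be non-empty")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if ages[0] < 0:
            raise ValueError("ages must be >= 0")
        if np.any(freqs < 0) or not np.all(np.isfinite(freqs)):
            raise ValueError("frequencies must be finite and >= 0")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "frequencies", freqs)

    def __len__(self) -> int:
        return int(self.ages.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"colony": self.colony, "age": self.ages, "frequency": self.frequencies}
        )


@dataclass(frozen=True)
class StandardizationSpec:
    """How to turn records into observed age frequencies.

    mode
        ``"proportion"`` (frequencies sum to 1) or ``"count"``
        (proportions multiplied by the total number of captures).
    zero_class_proportion
        Observed proportion of unaged 0-year juveniles among all
        captures.  When ``None`` it is inferred from any unaged records
        present; when given, the 0-class frequency is forced to this
        value and the tooth-aged classes rescaled to the remainder.
    """

    mode: str = "proportion"
    zero_class_proportion: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("proportion", "count"):
            raise ValueError("mode must be 'proportion' or 'count'")
        p = self.zero_class_proportion
        if p is not None and not (0.0 <= p <= 1.0):
            raise ValueError("zero_class_proportion must lie in [0, 1]")


def filter_records(records: Sequence[IndividualRecord]) -> list:
    """Drop certainty-C records (tooth quality too poor to age reliably)."""
    kept = [r for r in records if r.certainty != "C"]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("filter_records: dropped %d certainty-C record(s) of %d", n_dropped, len(records))
    return kept


def standardize(
    records: Sequence[IndividualRecord],
    spec: StandardizationSpec = StandardizationSpec(),
) -> AgeFrequencyData:
    """Standardize records into per-age observed frequencies.

    Tooth-aged records are tabulated into proportions per integer age.
    If a zero-class capture proportion ``p`` applies (given explicitly,
    or inferred from unaged-juvenile records), the 0-year class is set to
    ``p`` and the tooth-aged classes are rescaled to sum to ``1 - p``;
    tooth-aged 0-year records are then subsumed into the forced 0-class.
    In ``"count"`` mode the proportions are multiplied by the total
    number of captures.
    """
    records = list(records)
    if not records:
        raise ValueError("no usable ages: no records supplied")
    colonies = {r.colony for r in records}
    if len(colonies) > 1:
        raise ValueError(f"records span multiple colonies: {sorted(colonies)}")
    colony = colonies.pop()

    aged = [r for r in records if r.is_aged]
    n_unaged = len(records) - len(aged)
    n_total = len(records)
    if not aged:
        raise ValueError("no usable ages: all records are unaged juveniles")

    p = spec.zero_class_proportion
    if p is None and n_unaged > 0:
        p = n_unaged / n_total

    ages_obs, counts = np.unique([r.age_years for r in aged], return_counts=True)
    props = counts / counts.sum()

    if p is None:
        ages, freqs = ages_obs, props
    else:
        if p == 1.0:
            raise ValueError(
                "zero_class_proportion = 1 is inconsistent with tooth-aged records present"
            )
        # the observed capture proportion takes precedence over any
        # tooth-aged 0-year records, which fold into the forced 0-class
        keep = ages_obs >= 1
        if not np.all(keep):
            warnings.warn(
                "tooth-aged 0-year records are subsumed into the forced "
                "0-class proportion",
                stacklevel=2,
            )
        older = props[keep]
        if older.size == 0:
            raise ValueError("no usable ages above the corrected 0-class")
        older = older / older.sum() * (1.0 - p)
        ages = np.concatenate(([0], ages_obs[keep]))
        freqs = np.concatenate(([p], older))

    if spec.mode == "count":
        freqs = freqs * n_total

    return AgeFrequencyData(colony=colony, ages=ages, frequencies=freqs, n_total=n_total)


def _parse_age(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        s = value.strip()
        if s == "" or s.lower() == UNAGED:
            return None
        return int(float(s))
    return int(value)


def read_colony_csv(path: str | Path) -> dict:
    """Read colony data from CSV, in either of two dialects.

    Per-individual rows: columns ``colony, age_years, sex, certainty,
    phase`` (``age_years`` empty or ``unaged_juvenile`` for unaged pups;
    ``sex``/``certainty``/``phase`` optional).  Pre-tabulated rows:
    columns ``colony, age, count``, expanded into one record per
    individual.  Returns ``{colony: [IndividualRecord, ...]}``.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    out: dict = {}
    if {"colony", "age_years"} <= cols:
        for _, row in df.iterrows():
            rec = IndividualRecord(
                colony=str(row["colony"]),
                age_years=_parse_age(row["age_years"]),
                sex=str(row["sex"]) if "sex" in cols and pd.notna(row.get("sex")) else "unknown",
                certainty=str(row["certainty"]) if "certainty" in cols and pd.notna(row.get("certainty")) else "none",
                phase=str(row["phase"]) if "phase" in cols and pd.notna(row.get("phase")) else None,
            )
            out.setdefault(rec.colony, []).append(rec)
    elif {"colony", "age", "count"} <= cols:
        for _, row in df.iterrows():
            age = _parse_age(row["age"])
            for _ in range(int(row["count"])):
                rec = IndividualRecord(colony=str(row["colony"]), age_years=age)
                out.setdefault(rec.colony, []).append(rec)
    else:
        raise ValueError(
            "unrecognised CSV schema: need columns (colony, age_years, ...) "
            "or (colony, age, count)"
        )
    return out


def write_age_frequencies(data: Iterable[AgeFrequencyData], path: str | Path) -> None:
    """Write standardized age-frequency tables as CSV (colony, age, frequency)."""
    frames = [d.to_frame() for d in data] if not isinstance(data, AgeFrequencyData) else [data.to_frame()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
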