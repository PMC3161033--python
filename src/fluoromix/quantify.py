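"""Per-animal tumor-burden aggregation and group growth-curve summaries.

Tumor burden for one animal-day is the total DsRed abundance over
above-threshold pixels.  Longitudinal series are normalized per animal to the
day-0 measurement (ratio mode by default, difference mode optional) and
summarized per group and day as mean ± SEM over the animals still present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .unmix import ThresholdedMap

__all__ = [
    "AnimalRecord",
    "CohortTable",
    "total_dsred",
    "relative_series",
    "group_mean_sem",
    "growth_curve_table",
]

GROUPS = ("vehicle", "treated")


def total_dsred(tmap: ThresholdedMap) -> float:
    """Sum of masked DsRed abundance over above-threshold pixels.

    Returns 0 for an empty mask.  Negative masked abundances should not occur
    with a positive threshold; any that do are clipped to 0 with a warning so
    totals stay non-negative.
    """
    masked = tmap.masked
    if np.any(masked < 0):
        warnings.warn(
            "negative masked abundances clipped to 0 before totaling", stacklevel=2
        )
        masked = np.clip(masked, 0.0, None)
    return float(masked.sum())


@dataclass
class AnimalRecord:
    """One animal's group label and day → total-burden measurements.

    Missing animal-days (e.g. animals sacrificed at the tumor-size limit)
    are simply absent from ``measurements``, never recorded as zeros.
    """

    animal_id: str
    group: str
    measurements: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for day, total in self.measurements.items():
            if day < 0 or int(day) != day:
                raise ValueError(f"days must be non-negative integers, got {day}")
            if total < 0:
                raise ValueError(f"total burden must be non-negative, got {total}")

    @property
    def days(self) -> list[int]:
        return sorted(self.measurements)


def relative_series(
    record: AnimalRecord,
    baseline_day: int = 0,
    eps: float = 1e-9,
    mode: str = "ratio",
) -> dict[int, float]:
    """Burden series normalized to the baseline day.

    ``ratio`` mode (default): R(t) = T(t) / max(T(baseline), ε), matching the
    convention of reporting fluorescence "relative to day 0".  ``difference``
    mode: R(t) = T(t) − T(baseline).  A warning flags an active ε guard
    (zero or near-zero baseline).
    """
    if baseline_day not in record.measurements:
        raise ValueError(
            f"baseline day {baseline_day} missing for animal {record.animal_id}"
        )
    if eps <= 0:
        raise ValueError("eps must be positive")
    baseline = record.measurements[baseline_day]
    if mode == "ratio":
        denom = max(baseline, eps)
        if baseline < eps:
            warnings.warn(
                f"animal {record.animal_id}: baseline {baseline:.3g} below ε = {eps:.3g}; "
                "relative burden uses the ε guard",
                stacklevel=2,
            )
        return {day: t / denom for day, t in record.measurements.items()}
    if mode == "difference":
        return {day: t - baseline for day, t in record.measurements.items()}
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CohortTable:
    """All animals of a two-group study plus dosing metadata."""

    animals: list[AnimalRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.animal_id for a in self.animals]
        if len(set(ids)) != len(ids):
            raise ValueError("animal_ids must be unique")

    def group(self, name: str) -> list[AnimalRecord]:
        return [a for a in self.animals if a.group == name]

    def group_values(self, name: str, day: int) -> np.ndarray:
        """Burden values on one day for the animals of a group that have it."""
        return np.array(
            [a.measurements[day] for a in self.group(name) if day in a.measurements]
        )

    @property
    def days(self) -> list[int]:
        return sorted({d for a in self.animals for d in a.measurements})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "animal_id": a.animal_id,
                "group": a.group,
                "day": day,
                "total_dsred": a.measurements[day],
            }
            for a in self.animals
            for day in a.days
        ]
        return pd.DataFrame(rows, columns=["animal_id", "group", "day", "total_dsred"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "CohortTable":
        animals = []
        for (animal_id, group), sub in df.groupby(["animal_id", "group"], sort=True):
            animals.append(
                AnimalRecord(
                    str(animal_id),
                    str(group),
                    {int(r.day): float(r.total_dsred) for r in sub.itertuples()},
                )
            )
        return cls(animals, metadata=metadata or {})

    def relative(self, baseline_day: int = 0, eps: float = 1e-9, mode: str = "ratio") -> "CohortTable":
        """Cohort with every series normalized to the baseline day."""
        return CohortTable(
            [
                AnimalRecord(
                    a.animal_id,
                    a.group,
                    relative_series(a, baseline_day=baseline_day, eps=eps, mode=mode),
                )
                for a in self.animals
            ],
            metadata=dict(self.metadata),
        )


def group_mean_sem(cohort: CohortTable, group: str, day: int) -> tuple[float, float, int]:
    """Mean, SEM (sd/√n with sd using n−1) and n for one group-day."""
    values = cohort.group_values(group, day)
    n = values.size
    if n < 2:
        raise ValueError(
            f"SEM undefined for group {group!r} on day {day}: only {n} animal(s)"
        )
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(n)), int(n)


def growth_curve_table(cohort: CohortTable) -> pd.DataFrame:
    """Tidy per-group, per-day summary: columns group, day, mean, sem, n.

    Rows are ordered by group then day.  Groups with a single animal on a day
    get mean and n with sem = NaN (flagged unavailable).
    """
    rows = []
    for group in sorted({a.group for a in cohort.animals}):
        for day in cohort.days:
            values = cohort.group_values(group, day)
            if values.size == 0:
                continue
            sem = (
                float(values.std(ddof=1) / np.sqrt(values.size))
                if values.size >= 2
                else float("nan")
            )
            rows.append(
                {
                    "group": group,
                    "day": day,
                    "mean": float(values.mean()),
                    "sem": sem,
                    "n": int(values.size),
                }
            )
    return pd.DataFrame(rows, columns=["group", "day", "mean", "sem", "n"])
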