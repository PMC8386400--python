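"""Core domain types for the weekly self-report / monthly clinician-scale analysis.

The pipeline revolves around four record types:

* :class:`AsertResponse` — one weekly 10-item ordinal self-report (items scored
  0-4; four depressive, four manic, two nonspecific items) with derived
  subscores.
* :class:`ClinicalAssessment` — one clinician rating event carrying MADRS and
  YMRS totals (0-60 each) and the scale-based relapse labels derived from them.
* :class:`Patient` — roster entry with enrollment/exit dates.
* :class:`MatchedRecord` — a clinical assessment joined to its concurrent
  self-report (within +/-3 days) and, optionally, to lagged self-reports from
  the two preceding weeks.  This is the analysis row for every downstream
  stage.

All dates are calendar dates at day resolution; window arithmetic is in whole
days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "DEP_ITEMS",
    "MAN_ITEMS",
    "NSP_ITEMS",
    "MADRS_RELAPSE_THRESHOLD",
    "YMRS_RELAPSE_THRESHOLD",
    "ITEM_MIN",
    "ITEM_MAX",
    "AsertResponse",
    "ClinicalAssessment",
    "Patient",
    "MatchedRecord",
    "RunConfig",
]

# 0-based indices of the fixed item groups of the 10-item questionnaire.
DEP_ITEMS: tuple[int, ...] = (0, 1, 2, 3)
MAN_ITEMS: tuple[int, ...] = (4, 5, 6, 7)
NSP_ITEMS: tuple[int, ...] = (8, 9)

ITEM_MIN = 0
ITEM_MAX = 4

# Scale-based episode definitions: a depressive relapse is MADRS total >= 15,
# a manic relapse YMRS total >= 15; below threshold is the interepisode state.
MADRS_RELAPSE_THRESHOLD = 15
YMRS_RELAPSE_THRESHOLD = 15


@dataclass(frozen=True)
class AsertResponse:
    """A single complete weekly self-report.

    The delivery app only accepts complete questionnaires, so ``items`` always
    holds 10 integers in {0,...,4}; subscores are derived, never stored
    independently.
    """

    patient_id: str
    date: dt.date
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValueError(f"expected 10 items, got {len(self.items)}")
        for k, v in enumerate(self.items):
            if not (ITEM_MIN <= int(v) <= ITEM_MAX):
                raise ValueError(f"item q{k + 1} value {v} outside 0..4")
        object.__setattr__(self, "items", tuple(int(v) for v in self.items))

    @property
    def dep_sum(self) -> int:
        """Sum of the four depressive items (0-16)."""
        return sum(self.items[k] for k in DEP_ITEMS)

    @property
    def man_sum(self) -> int:
        """Sum of the four manic items (0-16)."""
        return sum(self.items[k] for k in MAN_ITEMS)

    @property
    def nsp_sum(self) -> int:
        """Sum of the two nonspecific items (0-8)."""
        return sum(self.items[k] for k in NSP_ITEMS)

    @property
    def depnsp_sum(self) -> int:
        """Depressive + nonspecific subscore (0-24), the depression predictor."""
        return self.dep_sum + self.nsp_sum


@dataclass(frozen=True)
class ClinicalAssessment:
    """One MADRS/YMRS rating event with derived relapse labels.

    Item-level scores are optional (not all deployments archive them); when
    present their sum must equal the stored total.
    """

    patient_id: str
    date: dt.date
    madrs_total: int
    ymrs_total: int
    madrs_items: Optional[tuple[int, ...]] = None
    ymrs_items: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not (0 <= self.madrs_total <= 60):
            raise ValueError(f"MADRS total {self.madrs_total} outside 0..60")
        if not (0 <= self.ymrs_total <= 60):
            raise ValueError(f"YMRS total {self.ymrs_total} outside 0..60")
        if self.madrs_items is not None:
            items = tuple(int(v) for v in self.madrs_items)
            if len(items) != 10:
                raise ValueError("MADRS item vector must have 10 entries")
            if sum(items) != self.madrs_total:
                raise ValueError(
                    f"MADRS items sum {sum(items)} != total {self.madrs_total}"
                )
            object.__setattr__(self, "madrs_items", items)
        if self.ymrs_items is not None:
            items = tuple(int(v) for v in self.ymrs_items)
            if len(items) != 11:
                raise ValueError("YMRS item vector must have 11 entries")
            if sum(items) != self.ymrs_total:
                raise ValueError(
                    f"YMRS items sum {sum(items)} != total {self.ymrs_total}"
                )
            object.__setattr__(self, "ymrs_items", items)

    @property
    def dep_relapse(self) -> bool:
        return self.madrs_total >= MADRS_RELAPSE_THRESHOLD

    @property
    def man_relapse(self) -> bool:
        return self.ymrs_total >= YMRS_RELAPSE_THRESHOLD


@dataclass(frozen=True)
class Patient:
    """Roster entry. ``weeks_in_study`` counts any started week as owed."""

    patient_id: str
    enrollment_date: dt.date
    exit_date: dt.date

    def __post_init__(self) -> None:
        if self.exit_date < self.enrollment_date:
            raise ValueError(
                f"patient {self.patient_id}: exit before enrollment"
            )

    @property
    def weeks_in_study(self) -> int:
        """floor((exit - enrollment)/7) + 1: a started week owes one report."""
        return (self.exit_date - self.enrollment_date).days // 7 + 1


@dataclass(frozen=True)
class MatchedRecord:
    """A clinical assessment with its concurrent and lagged self-reports.

    ``concurrent`` lies within +/-3 days of the assessment (unique matching);
    ``lag1`` lies 4-10 days before the assessment date and ``lag2`` 11-17 days
    before, both inclusive.
    """

    assessment: ClinicalAssessment
    concurrent: AsertResponse
    lag1: Optional[AsertResponse] = None
    lag2: Optional[AsertResponse] = None

    def __post_init__(self) -> None:
        if self.concurrent.patient_id != self.assessment.patient_id:
            raise ValueError("concurrent report from a different patient")
        if abs(self.delta_days) > 3:
            raise ValueError(
                f"concurrent report {self.delta_days} days from assessment"
            )
        for lag, lo, hi in ((self.lag1, 4, 10), (self.lag2, 11, 17)):
            if lag is None:
                continue
            if lag.patient_id != self.assessment.patient_id:
                raise ValueError("lagged report from a different patient")
            back = (self.assessment.date - lag.date).days
            if not (lo <= back <= hi):
                raise ValueError(
                    f"lagged report {back} days before assessment, "
                    f"expected {lo}..{hi}"
                )

    @property
    def patient_id(self) -> str:
        return self.assessment.patient_id

    @property
    def delta_days(self) -> int:
        """Concurrent report date minus assessment date (negative = before)."""
        return (self.concurrent.date - self.assessment.date).days


@dataclass
class RunConfig:
    """End-to-end run configuration with the study-design defaults.

    Defaults mirror the analysis design: +/-3-day matching, relapse thresholds
    15/15, 10,000 bootstrap resamples, 70:30 grouped splits repeated 999 times,
    and threshold calibration to 90% training specificity.
    """

    window_days: int = 3
    madrs_threshold: int = MADRS_RELAPSE_THRESHOLD
    ymrs_threshold: int = YMRS_RELAPSE_THRESHOLD
    bootstrap_resamples: int = 10_000
    split_ratio: float = 0.7
    split_repetitions: int = 999
    target_specificity: float = 0.90
    ladder: Optional[Sequence[dict]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_days < 0:
            raise ValueError("window_days must be >= 0")
        if self.bootstrap_resamples < 1:
            raise ValueError("bootstrap_resamples must be positive")
        if self.split_repetitions < 1:
            raise ValueError("split_repetitions must be positive")
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must lie in (0, 1)")
        if not (0.0 < self.target_specificity < 1.0):
            raise ValueError("target_specificity must lie in (0, 1)")
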