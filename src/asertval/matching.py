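"""Construction of the analysis dataset from raw report and assessment tables.

The matched dataset pairs each clinician assessment with at most one weekly
self-report no further than ``window_days`` (default 3) days away, with both
endpoints used at most once (unique matching).  Greedy nearest-first matching
realises this: enumerate eligible pairs within each patient, sort by
(|delta| ascending, report-before-assessment preferred, earlier assessment
date, earlier report date) and accept pairs whose endpoints are still unused.

Lagged self-reports from the windows 4-10 and 11-17 days before the
assessment are then attached (closest to the window centre, ties resolved to
the more recent report); lag attachment does not consume reports — a report
serving as one record's concurrent match may be another record's lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .domain import AsertResponse, ClinicalAssessment, MatchedRecord

__all__ = [
    "MatchingReport",
    "match_concurrent",
    "attach_lags",
    "filter_detection_cohort",
    "filter_new_relapses",
    "split_by_report_timing",
]

Outcome = Literal["dep", "man"]


@dataclass
class MatchingReport:
    """Counts describing one matching pass."""

    n_assessments: int = 0
    n_reports: int = 0
    n_matched: int = 0
    n_unmatched_assessments: int = 0
    n_lag1: int = 0
    n_lag2: int = 0
    per_patient_matches: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_assessments": self.n_assessments,
            "n_reports": self.n_reports,
            "n_matched": self.n_matched,
            "n_unmatched_assessments": self.n_unmatched_assessments,
            "n_lag1": self.n_lag1,
            "n_lag2": self.n_lag2,
            "per_patient_matches": dict(sorted(self.per_patient_matches.items())),
        }


def match_concurrent(
    asserts: Sequence[AsertResponse],
    assessments: Sequence[ClinicalAssessment],
    window_days: int = 3,
) -> tuple[list[MatchedRecord], MatchingReport]:
    """Unique nearest-first matching of self-reports to assessments.

    Matching is within patient only.  Assessments with no eligible report are
    counted in the report, not silently erased.  Output order is
    (patient_id, assessment date), independent of input row order.
    """
    report = MatchingReport(
        n_assessments=len(assessments), n_reports=len(asserts)
    )
    by_patient: dict[str, list[AsertResponse]] = {}
    for r in asserts:
        by_patient.setdefault(r.patient_id, []).append(r)

    assess_by_patient: dict[str, list[ClinicalAssessment]] = {}
    for a in assessments:
        assess_by_patient.setdefault(a.patient_id, []).append(a)

    matched: list[MatchedRecord] = []
    for pid in sorted(assess_by_patient):
        pat_assessments = sorted(assess_by_patient[pid], key=lambda a: a.date)
        pat_reports = sorted(by_patient.get(pid, []), key=lambda r: r.date)
        # All eligible pairs, then the fixed tie-broken greedy order:
        # |delta| ascending; report-before-assessment (delta < 0) preferred;
        # earlier assessment date; earlier report date.
        candidates = []
        for a in pat_assessments:
            for r in pat_reports:
                delta = (r.date - a.date).days
                if abs(delta) <= window_days:
                    candidates.append((abs(delta), 0 if delta < 0 else 1, a.date, r.date, a, r))
        candidates.sort(key=lambda c: c[:4])
        used_a: set[object] = set()
        used_r: set[object] = set()
        for _, _, _, _, a, r in candidates:
            if id(a) in used_a or id(r) in used_r:
                continue
            used_a.add(id(a))
            used_r.add(id(r))
            matched.append(MatchedRecord(a, r))
        report.per_patient_matches[pid] = len(used_a)

    matched.sort(key=lambda m: (m.patient_id, m.assessment.date))
    report.n_matched = len(matched)
    report.n_unmatched_assessments = len(assessments) - len(matched)
    return matched, report


def _closest_in_window(
    reports: Sequence[AsertResponse],
    assessment_date,
    lo_days_before: int,
    hi_days_before: int,
) -> Optional[AsertResponse]:
    """Report within [date-hi, date-lo] closest to the window centre.

    The centre is date - (lo+hi)/2 (7 or 14 days back); ties go to the more
    recent report.
    """
    centre = (lo_days_before + hi_days_before) / 2.0
    best: Optional[AsertResponse] = None
    best_key: Optional[tuple[float, int]] = None
    for r in reports:
        back = (assessment_date - r.date).days
        if not (lo_days_before <= back <= hi_days_before):
            continue
        key = (abs(back - centre), back)  # smaller back = more recent wins ties
        if best_key is None or key < best_key:
            best, best_key = r, key
    return best


def attach_lags(
    records: Sequence[MatchedRecord],
    asserts: Sequence[AsertResponse],
    report: Optional[MatchingReport] = None,
) -> list[MatchedRecord]:
    """Fill lag1 (4-10 days before) and lag2 (11-17 days before) per record."""
    by_patient: dict[str, list[AsertResponse]] = {}
    for r in asserts:
        by_patient.setdefault(r.patient_id, []).append(r)
    out: list[MatchedRecord] = []
    n1 = n2 = 0
    for m in records:
        reports = by_patient.get(m.patient_id, [])
        lag1 = _closest_in_window(reports, m.assessment.date, 4, 10)
        lag2 = _closest_in_window(reports, m.assessment.date, 11, 17)
        n1 += lag1 is not None
        n2 += lag2 is not None
        out.append(MatchedRecord(m.assessment, m.concurrent, lag1=lag1, lag2=lag2))
    if report is not None:
        report.n_lag1 = n1
        report.n_lag2 = n2
    return out


def _relapse_flag(record: MatchedRecord, outcome: Outcome) -> bool:
    if outcome == "dep":
        return record.assessment.dep_relapse
    if outcome == "man":
        return record.assessment.man_relapse
    raise ValueError(f"unknown outcome {outcome!r}")


def filter_detection_cohort(
    records: Sequence[MatchedRecord], outcome: Outcome
) -> list[MatchedRecord]:
    """Keep only patients contributing both relapse and nonrelapse records."""
    flags: dict[str, set[bool]] = {}
    for m in records:
        flags.setdefault(m.patient_id, set()).add(_relapse_flag(m, outcome))
    keep = {pid for pid, f in flags.items() if f == {True, False}}
    return [m for m in records if m.patient_id in keep]


def filter_new_relapses(
    records: Sequence[MatchedRecord], outcome: Outcome
) -> list[MatchedRecord]:
    """Keep nonrelapse records and relapses preceded by a nonrelapse scale.

    Within each patient's assessment order, consecutive relapses after the
    first of a run are removed; a relapse with no preceding assessment is
    removed too (it has no preceding scale to establish novelty).
    """
    by_patient: dict[str, list[MatchedRecord]] = {}
    for m in records:
        by_patient.setdefault(m.patient_id, []).append(m)
    out: list[MatchedRecord] = []
    for pid in sorted(by_patient):
        seq = sorted(by_patient[pid], key=lambda m: m.assessment.date)
        prev_flag: Optional[bool] = None
        for m in seq:
            flag = _relapse_flag(m, outcome)
            if not flag:
                out.append(m)
            elif prev_flag is False:
                out.append(m)
            prev_flag = flag
    return out


def split_by_report_timing(
    records: Sequence[MatchedRecord],
) -> tuple[list[MatchedRecord], list[MatchedRecord]]:
    """Partition by the sign of delta_days; delta 0 counts as 'before'."""
    before = [m for m in records if m.delta_days <= 0]
    after = [m for m in records if m.delta_days > 0]
    return before, after
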