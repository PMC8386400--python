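"""Matching: unique nearest-first pairing, lag windows, cohort filters."""

from __future__ import annotations

import datetime as dt
import itertools

import numpy as np
import pytest

from asertval.domain import AsertResponse, ClinicalAssessment
from asertval.matching import (
    attach_lags,
    filter_detection_cohort,
    filter_new_relapses,
    match_concurrent,
    split_by_report_timing,
)

D = dt.date
BASE = D(2020, 1, 1)


def day(n: int) -> dt.date:
    return BASE + dt.timedelta(days=n)


def rep(pid: str, n: int, items=(0,) * 10) -> AsertResponse:
    return AsertResponse(pid, day(n), items)


def assess(pid: str, n: int, madrs=0, ymrs=0) -> ClinicalAssessment:
    return ClinicalAssessment(pid, day(n), madrs, ymrs)


class TestMatchConcurrent:
    def test_nearest_report_wins(self):
        # assessment day 10; reports days 6, 8, 13 -> day 8 (|d|=2; day 6 is
        # out of window at |d|=4; day 13 eligible but farther)
        records, report = match_concurrent(
            [rep("p", 6), rep("p", 8), rep("p", 13)], [assess("p", 10)]
        )
        assert len(records) == 1
        assert records[0].concurrent.date == day(8)
        assert report.n_matched == 1 and report.n_unmatched_assessments == 0

    def test_no_reports_all_unmatched(self):
        records, report = match_concurrent([], [assess("p", 10), assess("p", 40)])
        assert records == []
        assert report.n_unmatched_assessments == 2

    def test_tie_prefers_report_before_assessment(self):
        # assessments days 10 and 12, single report day 11: |d| = 1 both ways;
        # report-before-assessment wins, so the day-12 assessment is matched
        records, report = match_concurrent(
            [rep("p", 11)], [assess("p", 10), assess("p", 12)]
        )
        assert len(records) == 1
        assert records[0].assessment.date == day(12)
        assert records[0].delta_days == -1

    def test_matching_is_within_patient(self):
        records, _ = match_concurrent([rep("a", 10)], [assess("b", 10)])
        assert records == []

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        reports = [rep(f"p{i % 3}", int(n)) for i, n in enumerate(rng.integers(0, 60, 20))]
        # drop duplicate (pid, date)
        seen = set()
        reports = [
            r for r in reports
            if (r.patient_id, r.date) not in seen and not seen.add((r.patient_id, r.date))
        ]
        assessments = [assess(f"p{i % 3}", int(n)) for i, n in enumerate([5, 12, 33, 48])]
        a, _ = match_concurrent(reports, assessments)
        b, _ = match_concurrent(reports[::-1], assessments[::-1])
        assert a == b

    def test_window_monotonicity(self):
        rng = np.random.default_rng(11)
        reports, assessments, seen = [], [], set()
        for _ in range(25):
            pid, n = f"p{rng.integers(0, 4)}", int(rng.integers(0, 50))
            if (pid, n, "r") not in seen:
                seen.add((pid, n, "r"))
                reports.append(rep(pid, n))
        for _ in range(15):
            pid, n = f"p{rng.integers(0, 4)}", int(rng.integers(0, 50))
            if (pid, n, "a") not in seen:
                seen.add((pid, n, "a"))
                assessments.append(assess(pid, n))
        counts = [
            match_concurrent(reports, assessments, window_days=w)[1].n_matched
            for w in range(0, 4)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] > 0

    def test_uniqueness_and_brute_force_eligibility(self):
        """Every matched pair is brute-force eligible; no endpoint is reused;
        greedy order reproduced by an independent reference implementation."""
        rng = np.random.default_rng(23)
        for trial in range(10):
            reports, assessments = [], []
            seen = set()
            for _ in range(int(rng.integers(5, 30))):
                pid, n = f"p{rng.integers(0, 3)}", int(rng.integers(0, 40))
                if (pid, n) not in seen:
                    seen.add((pid, n))
                    reports.append(rep(pid, n))
            seen = set()
            for _ in range(int(rng.integers(3, 20))):
                pid, n = f"p{rng.integers(0, 3)}", int(rng.integers(0, 40))
                if (pid, n) not in seen:
                    seen.add((pid, n))
                    assessments.append(assess(pid, n))

            records, _ = match_concurrent(reports, assessments, window_days=3)

            # Independent reference: exhaustive pair enumeration + greedy.
            eligible = [
                (a, r)
                for a, r in itertools.product(assessments, reports)
                if a.patient_id == r.patient_id
                and abs((r.date - a.date).days) <= 3
            ]
            order = sorted(
                eligible,
                key=lambda ar: (
                    abs((ar[1].date - ar[0].date).days),
                    0 if ar[1].date < ar[0].date else 1,
                    ar[0].patient_id,
                    ar[0].date,
                    ar[1].date,
                ),
            )
            used_a, used_r, expected = set(), set(), set()
            for a, r in order:
                ka, kr = (a.patient_id, a.date), (r.patient_id, r.date)
                if ka in used_a or kr in used_r:
                    continue
                used_a.add(ka)
                used_r.add(kr)
                expected.add((ka, kr))
            got = {
                ((m.assessment.patient_id, m.assessment.date),
                 (m.concurrent.patient_id, m.concurrent.date))
                for m in records
            }
            assert got == expected
            assert len({g[0] for g in got}) == len(got)
            assert len({g[1] for g in got}) == len(got)


class TestAttachLags:
    def test_lag1_closest_to_week_centre(self):
        # assessment day 30; reports days 23 and 26: |23-23|=0 beats |26-23|=3
        records, _ = match_concurrent([rep("p", 30), rep("p", 23), rep("p", 26)],
                                      [assess("p", 30)])
        out = attach_lags(records, [rep("p", 30), rep("p", 23), rep("p", 26)])
        assert out[0].lag1.date == day(23)

    def test_missing_window_yields_absent_lag(self):
        records, _ = match_concurrent([rep("p", 30)], [assess("p", 30)])
        out = attach_lags(records, [rep("p", 30)])
        assert out[0].lag1 is None and out[0].lag2 is None

    def test_lag1_tie_goes_to_more_recent(self):
        # reports at date-6 and date-8: both distance 1 from date-7; more
        # recent (date-6) wins
        reports = [rep("p", 30), rep("p", 24), rep("p", 22)]
        records, _ = match_concurrent(reports, [assess("p", 30)])
        out = attach_lags(records, reports)
        assert out[0].lag1.date == day(24)

    def test_concurrent_report_can_serve_as_lag_elsewhere(self):
        reports = [rep("p", 7), rep("p", 14)]
        assessments = [assess("p", 7), assess("p", 14)]
        records, _ = match_concurrent(reports, assessments)
        out = attach_lags(records, reports)
        later = [m for m in out if m.assessment.date == day(14)][0]
        assert later.lag1 is not None and later.lag1.date == day(7)

    def test_lag_counts_recorded(self):
        reports = [rep("p", 30), rep("p", 23), rep("p", 16)]
        records, report = match_concurrent(reports, [assess("p", 30)])
        attach_lags(records, reports, report)
        assert report.n_lag1 == 1 and report.n_lag2 == 1


class TestDetectionCohortFilter:
    def test_patient_without_relapse_excluded(self):
        records, _ = match_concurrent(
            [rep("p", 0), rep("p", 28)],
            [assess("p", 0, madrs=5), assess("p", 28, madrs=10)],
        )
        assert filter_detection_cohort(records, "dep") == []

    def test_patient_with_both_states_included(self):
        records, _ = match_concurrent(
            [rep("p", 0), rep("p", 28)],
            [assess("p", 0, madrs=5), assess("p", 28, madrs=20)],
        )
        assert len(filter_detection_cohort(records, "dep")) == 2

    def test_empty_input(self):
        assert filter_detection_cohort([], "man") == []


class TestNewRelapseFilter:
    def _records(self, labels: str):
        reports = [rep("p", 28 * i) for i in range(len(labels))]
        assessments = [
            assess("p", 28 * i, madrs=20 if c == "R" else 5)
            for i, c in enumerate(labels)
        ]
        records, _ = match_concurrent(reports, assessments)
        return sorted(records, key=lambda m: m.assessment.date)

    def test_run_of_relapses_keeps_first_only(self):
        kept = filter_new_relapses(self._records("NRRNR"), "dep")
        dates = sorted(m.assessment.date for m in kept)
        # positions 1,2,4,5 kept (0-based 0,1,3,4); the position-3 relapse
        # (second in its run) is dropped
        assert dates == [day(0), day(28), day(84), day(112)]

    def test_all_nonrelapse_unchanged(self):
        records = self._records("NNNN")
        assert filter_new_relapses(records, "dep") == records

    def test_leading_relapse_dropped(self):
        kept = filter_new_relapses(self._records("RN"), "dep")
        assert [m.assessment.date for m in kept] == [day(28)]


class TestTimingSplit:
    def test_partition_by_delta_sign(self):
        reports = [rep("p", 8), rep("p", 31), rep("p", 56)]
        assessments = [assess("p", 10), assess("p", 28), assess("p", 56)]
        records, _ = match_concurrent(reports, assessments)
        before, after = split_by_report_timing(records)
        deltas_before = sorted(m.delta_days for m in before)
        deltas_after = sorted(m.delta_days for m in after)
        assert deltas_before == [-2, 0]  # delta 0 counts as 'before'
        assert deltas_after == [3]
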