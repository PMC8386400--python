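"""Domain types and CSV round-trips."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asertval.domain import (
    AsertResponse,
    ClinicalAssessment,
    MatchedRecord,
    Patient,
    RunConfig,
)
from asertval.io import (
    TableFormatError,
    load_config,
    read_asert_table,
    read_clinical_table,
    read_matched_table,
    read_patient_table,
    save_config,
    write_asert_table,
    write_clinical_table,
    write_matched_table,
    write_patient_table,
)

D = dt.date


class TestAsertResponse:
    def test_maximal_depressive_block(self):
        r = AsertResponse("p1", D(2020, 1, 6), (4, 4, 4, 4, 0, 0, 0, 0, 0, 0))
        assert (r.dep_sum, r.man_sum, r.nsp_sum, r.depnsp_sum) == (16, 0, 0, 16)

    def test_all_zero_items(self):
        r = AsertResponse("p1", D(2020, 1, 6), (0,) * 10)
        assert (r.dep_sum, r.man_sum, r.nsp_sum, r.depnsp_sum) == (0, 0, 0, 0)

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ValueError, match="q3"):
            AsertResponse("p1", D(2020, 1, 6), (0, 0, 5, 0, 0, 0, 0, 0, 0, 0))

    @settings(max_examples=200, derandomize=True)
    @given(items=st.lists(st.integers(0, 4), min_size=10, max_size=10))
    def test_subscore_arithmetic(self, items):
        r = AsertResponse("p", D(2021, 3, 1), tuple(items))
        assert r.dep_sum == sum(items[:4])
        assert r.man_sum == sum(items[4:8])
        assert r.nsp_sum == sum(items[8:])
        assert r.depnsp_sum == r.dep_sum + r.nsp_sum


class TestClinicalAssessment:
    @pytest.mark.parametrize(
        "madrs,ymrs,dep,man",
        [(15, 0, True, False), (14, 0, False, False), (0, 15, False, True),
         (60, 60, True, True)],
    )
    def test_relapse_thresholds(self, madrs, ymrs, dep, man):
        a = ClinicalAssessment("p", D(2020, 1, 1), madrs, ymrs)
        assert a.dep_relapse is dep and a.man_relapse is man

    def test_item_sum_consistency_accepted(self):
        a = ClinicalAssessment("p", D(2020, 1, 1), 10, 0, madrs_items=(1,) * 10)
        assert a.madrs_items == (1,) * 10

    def test_item_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ClinicalAssessment("p", D(2020, 1, 1), 9, 0, madrs_items=(1,) * 10)

    def test_total_range_enforced(self):
        with pytest.raises(ValueError):
            ClinicalAssessment("p", D(2020, 1, 1), 61, 0)


class TestPatient:
    @pytest.mark.parametrize(
        "days,weeks", [(0, 1), (6, 1), (7, 2), (13, 2), (70, 11)]
    )
    def test_weeks_in_study_counts_started_weeks(self, days, weeks):
        p = Patient("p", D(2020, 1, 6), D(2020, 1, 6) + dt.timedelta(days=days))
        assert p.weeks_in_study == weeks

    def test_exit_before_enrollment_rejected(self):
        with pytest.raises(ValueError):
            Patient("p", D(2020, 2, 1), D(2020, 1, 1))


class TestMatchedRecordInvariants:
    def test_window_violation_rejected(self):
        a = ClinicalAssessment("p", D(2020, 1, 10), 5, 3)
        far = AsertResponse("p", D(2020, 1, 1), (0,) * 10)
        with pytest.raises(ValueError):
            MatchedRecord(a, far)

    def test_lag_window_enforced(self):
        a = ClinicalAssessment("p", D(2020, 1, 20), 5, 3)
        conc = AsertResponse("p", D(2020, 1, 20), (0,) * 10)
        bad_lag = AsertResponse("p", D(2020, 1, 18), (0,) * 10)  # 2 days back
        with pytest.raises(ValueError):
            MatchedRecord(a, conc, lag1=bad_lag)


def _random_asserts(rng, n_patients=5, n_per=8):
    out = []
    for i in range(n_patients):
        base = D(2020, 1, 6) + dt.timedelta(days=int(rng.integers(0, 100)))
        for w in range(n_per):
            out.append(
                AsertResponse(
                    f"p{i}",
                    base + dt.timedelta(days=7 * w),
                    tuple(int(v) for v in rng.integers(0, 5, size=10)),
                )
            )
    return sorted(out, key=lambda r: (r.patient_id, r.date))


class TestRoundTrips:
    def test_asert_round_trip(self, tmp_path):
        import numpy as np

        rng = np.random.default_rng(5)
        records = _random_asserts(rng)
        path = tmp_path / "asert.csv"
        write_asert_table(records, path)
        assert read_asert_table(path) == records

    def test_clinical_round_trip_with_items(self, tmp_path):
        import numpy as np

        rng = np.random.default_rng(6)
        records = []
        for i in range(4):
            m_items = tuple(int(v) for v in rng.integers(0, 5, size=10))
            y_items = tuple(int(v) for v in rng.integers(0, 4, size=11))
            records.append(
                ClinicalAssessment(
                    f"p{i}",
                    D(2020, 2, 1) + dt.timedelta(days=28 * i),
                    sum(m_items),
                    sum(y_items),
                    madrs_items=m_items,
                    ymrs_items=y_items,
                )
            )
        path = tmp_path / "clinical.csv"
        write_clinical_table(records, path)
        assert read_clinical_table(path) == records

    def test_patient_round_trip(self, tmp_path):
        patients = [
            Patient("a", D(2020, 1, 6), D(2021, 1, 3)),
            Patient("b", D(2020, 3, 2), D(2020, 9, 7)),
        ]
        path = tmp_path / "patients.csv"
        write_patient_table(patients, path)
        assert read_patient_table(path) == patients

    def test_matched_round_trip(self, tmp_path, matched_small):
        records, _, _ = matched_small
        path = tmp_path / "matched.csv"
        write_matched_table(records, path)
        assert read_matched_table(path) == list(records)

    def test_empty_matched_writes_header_only(self, tmp_path):
        path = tmp_path / "matched.csv"
        write_matched_table([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("patient_id,")
        assert read_matched_table(path) == []

    def test_absent_lag_cells_are_empty_not_zero(self, tmp_path):
        a = ClinicalAssessment("p", D(2020, 1, 20), 5, 3)
        conc = AsertResponse("p", D(2020, 1, 19), (1,) * 10)
        write_matched_table([MatchedRecord(a, conc)], tmp_path / "m.csv")
        header, row = (tmp_path / "m.csv").read_text().strip().splitlines()
        cols = dict(zip(header.split(","), row.split(",")))
        assert cols["lag1_date"] == "" and cols["lag1_q1"] == ""


class TestReaderErrors:
    def test_missing_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("patient_id,date,q1\np,2020-01-01,0\n")
        with pytest.raises(TableFormatError, match="missing column"):
            read_asert_table(p)

    def test_out_of_range_reported_with_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        header = "patient_id,date," + ",".join(f"q{k}" for k in range(1, 11))
        p.write_text(header + "\np,2020-01-01,0,0,5,0,0,0,0,0,0,0\n")
        with pytest.raises(TableFormatError, match="row 2"):
            read_asert_table(p)

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        header = "patient_id,date," + ",".join(f"q{k}" for k in range(1, 11))
        row = "p,2020-01-01," + ",".join("0" for _ in range(10))
        p.write_text(header + "\n" + row + "\n" + row + "\n")
        with pytest.raises(TableFormatError, match="duplicate"):
            read_asert_table(p)

    def test_unparseable_date(self, tmp_path):
        p = tmp_path / "bad.csv"
        header = "patient_id,date," + ",".join(f"q{k}" for k in range(1, 11))
        p.write_text(header + "\np,01/02/2020," + ",".join("0" * 1 for _ in range(10)) + "\n")
        with pytest.raises(TableFormatError, match="date"):
            read_asert_table(p)


class TestRunConfig:
    def test_defaults_mirror_design(self):
        c = RunConfig()
        assert c.window_days == 3
        assert c.madrs_threshold == 15 and c.ymrs_threshold == 15
        assert c.bootstrap_resamples == 10_000
        assert c.split_ratio == 0.7 and c.split_repetitions == 999
        assert c.target_specificity == 0.90

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"split_repetitions": 0},
            {"bootstrap_resamples": 0},
            {"split_ratio": 1.0},
            {"target_specificity": 0.0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RunConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        c = RunConfig(seed=7, bootstrap_resamples=123)
        save_config(c, tmp_path / "run.yaml")
        assert load_config(tmp_path / "run.yaml") == c

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "run.yaml").write_text("bogus_key: 1\n")
        with pytest.raises(TableFormatError, match="bogus_key"):
            load_config(tmp_path / "run.yaml")
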