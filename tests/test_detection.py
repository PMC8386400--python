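"""Relapse detection: features, calibration, metrics, holdout, dominance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from asertval.detection import (
    DetectionModelSpec,
    build_feature_table,
    calibrate_threshold,
    default_ladder,
    evaluate,
    fit_logistic_mixed,
    make_split_plan,
    model_selection_ladder,
    predict_prob,
    repeated_split_validation,
    summarize_metrics,
)


def _feature_frame(seed=0, m=25, nper=14, slope=0.6, lag_slope=0.0):
    """Synthetic feature table shaped like the matched analysis frame."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(m):
        u = rng.normal(0, 0.6)
        for j in range(nper):
            depnsp = float(rng.integers(0, 25))
            lag1 = float(rng.integers(0, 25))
            lag2 = float(rng.integers(0, 25))
            eta = -4.5 + slope * depnsp + lag_slope * lag1 + u
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "dep_relapse": int(rng.random() < expit(eta)),
                    "man_relapse": 0,
                    "depnsp_sum": depnsp,
                    "man_sum": float(rng.integers(0, 17)),
                    "dep_sum": depnsp,
                    "nsp_sum": 0.0,
                    "lag1_depnsp_sum": lag1,
                    "lag2_depnsp_sum": lag2,
                    "lag1_man_sum": np.nan,
                    "lag2_man_sum": np.nan,
                }
            )
    return pd.DataFrame(rows)


class TestModelSpec:
    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown term"):
            DetectionModelSpec("dep", ("bogus",))

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            DetectionModelSpec("dep", ())

    def test_default_ladders_simple_to_complex(self):
        dep = default_ladder("dep")
        assert dep[0].random_structure == "none"
        assert all(s.random_structure == "intercept" for s in dep[1:])
        assert len(dep[-1].terms) == 3
        man = default_ladder("man")
        assert man[-1].terms == ("man_t", "man_t-1")


class TestBuildFeatureTable:
    def test_current_week_spec_keeps_every_row(self):
        df = _feature_frame()
        rows = build_feature_table(df, DetectionModelSpec("dep", ("depnsp_t",)))
        assert len(rows) == len(df)

    def test_missing_lag_rows_dropped(self):
        df = _feature_frame()
        df.loc[df.index[:7], "lag1_depnsp_sum"] = np.nan
        rows = build_feature_table(
            df, DetectionModelSpec("dep", ("depnsp_t", "depnsp_t-1"))
        )
        assert len(rows) == len(df) - 7

    def test_label_and_feature_values(self):
        df = pd.DataFrame(
            [
                {
                    "patient_id": "p",
                    "dep_relapse": 1,  # MADRS 20 -> relapse
                    "depnsp_sum": 18.0,
                }
            ]
        )
        rows = build_feature_table(df, DetectionModelSpec("dep", ("depnsp_t",)))
        assert rows.iloc[0]["label"] == 1
        assert rows.iloc[0]["depnsp_sum"] == 18.0


class TestCalibrateThreshold:
    def test_ten_negatives_target_ninety(self):
        # negatives at 0.05, 0.15, ..., 0.95: the smallest threshold leaving
        # 9/10 negatives below it is the midpoint of the top two
        neg = np.arange(0.05, 1.0, 0.10)
        labels = np.zeros(10, dtype=int)
        t = calibrate_threshold(neg, labels, 0.90)
        assert 0.85 < t <= 0.95
        assert np.sum(neg < t) == 9
        assert np.sum(neg < t) / 10 == pytest.approx(0.9)

    def test_all_negative_probs_zero(self):
        probs = np.array([0.0, 0.0, 0.0, 0.6, 0.7])
        labels = np.array([0, 0, 0, 1, 1])
        t = calibrate_threshold(probs, labels, 0.90)
        assert t > 0.0
        assert np.all(probs[labels == 1] >= t)  # sensitivity unharmed

    def test_target_one_exceeds_max_negative(self):
        probs = np.array([0.2, 0.5, 0.8])
        labels = np.zeros(3, dtype=int)
        t = calibrate_threshold(probs, labels, 1.0 - 1e-12)
        assert t > 0.8

    def test_minimality_against_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            probs = rng.random(30)
            labels = (rng.random(30) < 0.3).astype(int)
            if labels.sum() == 30:
                labels[0] = 0
            target = rng.choice([0.5, 0.8, 0.9, 0.95])
            t = calibrate_threshold(probs, labels, target)
            neg = probs[labels == 0]
            spec = np.sum(neg < t) / len(neg)
            assert spec >= target
            # no strictly smaller candidate achieves the target
            distinct = np.unique(neg)
            cands = np.concatenate(
                [[0.0], (distinct[:-1] + distinct[1:]) / 2,
                 [np.nextafter(distinct[-1], np.inf)]]
            )
            for c in cands[cands < t]:
                assert np.sum(neg < c) / len(neg) < target

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(np.array([0.5]), np.array([1]), 0.9)


class TestEvaluate:
    def test_all_remission_baseline_depression(self):
        # 1121 assessments, 195 relapses: predicting remission everywhere
        # scores (1121-195)/1121 = 0.826 accuracy at zero sensitivity
        labels = np.zeros(1121, dtype=int)
        labels[:195] = 1
        m = evaluate(np.zeros(1121), labels, threshold=0.5)
        assert m.accuracy == pytest.approx(926 / 1121, abs=1e-12)
        assert m.accuracy == pytest.approx(0.826, abs=5e-4)
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_all_remission_baseline_mania(self):
        labels = np.zeros(635, dtype=int)
        labels[:63] = 1
        m = evaluate(np.zeros(635), labels, threshold=0.5)
        assert m.accuracy == pytest.approx(572 / 635, abs=1e-12)
        assert m.accuracy == pytest.approx(0.900, abs=1e-3)

    def test_perfect_ranking_gives_auroc_one(self):
        labels = np.array([0, 0, 1, 1])
        m = evaluate(np.array([0.1, 0.2, 0.8, 0.9]), labels, 0.5)
        assert m.auroc == 1.0

    def test_auroc_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(7)
        for n in (20, 200, 1000):
            probs = rng.integers(0, 10, size=n) / 10.0  # heavy ties
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.min() == labels.max():
                labels[:2] = [0, 1]
            m = evaluate(probs, labels, 0.5)
            pos = probs[labels == 1][:, None]
            neg = probs[labels == 0][None, :]
            brute = (np.sum(pos > neg) + 0.5 * np.sum(pos == neg)) / (
                pos.size * neg.size / 1
            )
            brute = (np.sum(pos > neg) + 0.5 * np.sum(pos == neg)) / (
                (labels == 1).sum() * (labels == 0).sum()
            )
            assert m.auroc == pytest.approx(brute, abs=1e-12)

    def test_metric_identities(self):
        rng = np.random.default_rng(8)
        probs = rng.random(100)
        labels = (rng.random(100) < 0.4).astype(int)
        m = evaluate(probs, labels, 0.6)
        total = m.tp + m.fp + m.tn + m.fn
        assert total == 100
        assert m.accuracy == (m.tp + m.tn) / total
        assert m.sensitivity == m.tp / (m.tp + m.fn)
        assert m.specificity == m.tn / (m.tn + m.fp)

    def test_single_class_flags_undefined_auroc(self):
        m = evaluate(np.array([0.1, 0.9]), np.array([0, 0]), 0.5)
        assert not m.auroc_defined


class TestSplitPlan:
    def test_seventy_thirty_counts(self):
        pids = np.repeat([f"p{i}" for i in range(8)], 10)
        rng = np.random.default_rng(0)
        plan = make_split_plan(pids, 0.7, rng)
        for i in range(8):
            mask = pids == f"p{i}"
            assert plan.train_mask[mask].sum() == 7
            assert (~plan.train_mask[mask]).sum() == 3

    def test_single_record_patient_goes_to_training(self):
        pids = np.array(["a", "a", "b"])
        plan = make_split_plan(pids, 0.7, np.random.default_rng(0))
        assert plan.train_mask[2]

    def test_both_sets_nonempty_for_two_records(self):
        pids = np.array(["a", "a"])
        for seed in range(5):
            plan = make_split_plan(pids, 0.7, np.random.default_rng(seed))
            assert plan.train_mask.sum() == 1


class TestLogisticMixedDetection:
    def test_sign_recovery_and_training_auroc(self):
        df = _feature_frame(seed=1)
        spec = DetectionModelSpec("dep", ("depnsp_t",))
        rows = build_feature_table(df, spec)
        model = fit_logistic_mixed(rows, spec)
        assert model.coef_[0] > 0
        p = predict_prob(model, rows, spec)
        m = evaluate(p, rows["label"].to_numpy(), 0.5)
        assert m.auroc > 0.9

    def test_single_class_rejected(self):
        df = _feature_frame(seed=2)
        df["dep_relapse"] = 0
        spec = DetectionModelSpec("dep", ("depnsp_t",))
        rows = build_feature_table(df, spec)
        with pytest.raises(ValueError):
            fit_logistic_mixed(rows, spec)


class TestRepeatedSplitValidation:
    def test_reproducible_and_counts(self):
        df = _feature_frame(seed=3, m=15, nper=10)
        spec = DetectionModelSpec("dep", ("depnsp_t",))
        rows = build_feature_table(df, spec)
        r1 = repeated_split_validation(rows, spec, reps=5, seed=42)
        r2 = repeated_split_validation(rows, spec, reps=5, seed=42)
        assert r1.to_csv() == r2.to_csv()  # byte-for-byte
        ok = r1[~r1["failed"]]
        assert len(ok) == 10  # 5 train + 5 test rows
        assert set(ok["set"]) == {"train", "test"}

    def test_training_specificity_meets_target_every_repetition(self):
        df = _feature_frame(seed=4, m=20, nper=12)
        spec = DetectionModelSpec("dep", ("depnsp_t",))
        rows = build_feature_table(df, spec)
        res = repeated_split_validation(rows, spec, reps=20, seed=9,
                                        target_specificity=0.90)
        train = res[(~res["failed"]) & (res["set"] == "train")]
        assert len(train) == 20
        assert (train["specificity"] >= 0.90).all()

    def test_label_permutation_null_auroc(self):
        df = _feature_frame(seed=5, m=20, nper=12)
        rng = np.random.default_rng(0)
        # permute labels within patients: any apparent signal is chance
        df["dep_relapse"] = df.groupby("patient_id")["dep_relapse"].transform(
            lambda s: rng.permutation(s.to_numpy())
        )
        spec = DetectionModelSpec("dep", ("depnsp_t",))
        rows = build_feature_table(df, spec)
        res = repeated_split_validation(rows, spec, reps=30, seed=2)
        test = res[(~res["failed"]) & (res["set"] == "test")]
        assert test["auroc"].mean() == pytest.approx(0.5, abs=0.1)

    def test_summary_structure(self):
        df = _feature_frame(seed=6, m=12, nper=8)
        spec = DetectionModelSpec("dep", ("depnsp_t",))
        rows = build_feature_table(df, spec)
        res = repeated_split_validation(rows, spec, reps=5, seed=1)
        s = summarize_metrics(res)
        assert set(s["test"]) <= {"accuracy", "sensitivity", "specificity", "auroc"}
        assert 0 <= s["test"]["auroc"]["mean"] <= 1


class TestModelSelectionLadder:
    def test_single_element_ladder_returned_unchanged(self):
        df = _feature_frame(seed=7, m=10, nper=8)
        spec = DetectionModelSpec("dep", ("depnsp_t",))
        best, table = model_selection_ladder(df, [spec], reps=3, seed=0)
        assert best == spec
        assert table.empty

    def test_pure_noise_feature_not_adopted(self):
        # lag1 column is independent noise: the complex model should win
        # about half the splits, far from the 90% dominance bar
        df = _feature_frame(seed=8, m=25, nper=14, lag_slope=0.0)
        ladder = [
            DetectionModelSpec("dep", ("depnsp_t",)),
            DetectionModelSpec("dep", ("depnsp_t", "depnsp_t-1")),
        ]
        best, table = model_selection_ladder(df, ladder, reps=40, seed=3)
        assert best == ladder[0]
        assert 0.1 < table.iloc[0]["win_fraction"] < 0.9

    def test_informative_lag_adopted(self):
        # lag1 carries strong independent signal: complex model dominates
        df = _feature_frame(seed=9, m=30, nper=14, slope=0.35, lag_slope=0.35)
        ladder = [
            DetectionModelSpec("dep", ("depnsp_t",)),
            DetectionModelSpec("dep", ("depnsp_t", "depnsp_t-1")),
        ]
        best, table = model_selection_ladder(df, ladder, reps=40, seed=4)
        assert best == ladder[1]
        assert table.iloc[0]["win_fraction"] >= 0.9
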