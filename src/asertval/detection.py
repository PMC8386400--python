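"""Scale-based relapse detection from weekly self-reports.

The detector is a logistic mixed model of the relapse label (clinician total
at or above threshold) on self-report subscores from the assessment week and
optionally from one and two weeks before.  Evaluation follows a repeated
grouped holdout design: each patient's records are split 70:30 into train
and test, the model is fitted on the training set, its decision threshold is
calibrated on the training ROC to a target specificity (default 90%), and
accuracy / sensitivity / specificity / AUROC are recorded for both sets.
The split-fit-calibrate-evaluate cycle is repeated (default 999 times) to
yield performance distributions, and nested model specifications are
compared by a dominance rule: the more complex model replaces the simpler
one only if its test AUROC is strictly better in at least 90% of shared
splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .mixed import ConvergenceError, LogisticMixedClassifier

__all__ = [
    "DetectionModelSpec",
    "DetectionMetrics",
    "SplitPlan",
    "TERM_COLUMNS",
    "default_ladder",
    "build_feature_table",
    "fit_logistic_mixed",
    "predict_prob",
    "calibrate_threshold",
    "evaluate",
    "repeated_split_validation",
    "model_selection_ladder",
]

logger = logging.getLogger(__name__)

Outcome = Literal["dep", "man"]

# Fixed-effect term names -> matched-table columns.
TERM_COLUMNS: dict[str, str] = {
    "depnsp_t": "depnsp_sum",
    "depnsp_t-1": "lag1_depnsp_sum",
    "depnsp_t-2": "lag2_depnsp_sum",
    "man_t": "man_sum",
    "man_t-1": "lag1_man_sum",
    "man_t-2": "lag2_man_sum",
    "dep_t": "dep_sum",
    "nsp_t": "nsp_sum",
}

_LABEL_COLUMN = {"dep": "dep_relapse", "man": "man_relapse"}


@dataclass(frozen=True)
class DetectionModelSpec:
    """One candidate model: outcome, fixed-effect terms, random structure."""

    outcome: Outcome
    terms: tuple[str, ...]
    random_structure: str = "intercept"  # none | intercept | slope

    def __post_init__(self) -> None:
        if self.outcome not in _LABEL_COLUMN:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not self.terms:
            raise ValueError("at least one fixed-effect term is required")
        unknown = [t for t in self.terms if t not in TERM_COLUMNS]
        if unknown:
            raise ValueError(f"unknown term(s): {', '.join(unknown)}")
        if self.random_structure not in ("none", "intercept", "slope"):
            raise ValueError(f"unknown random structure {self.random_structure!r}")

    @property
    def label(self) -> str:
        re_part = {"none": "", "intercept": " + (1|patient)",
                   "slope": " + (1+x|patient)"}[self.random_structure]
        return f"{self.outcome} ~ {' + '.join(self.terms)}{re_part}"


@dataclass
class DetectionMetrics:
    """Confusion-matrix metrics at a calibrated threshold, plus AUROC."""

    set_label: str
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    auroc: float
    auroc_defined: bool = True

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def as_dict(self) -> dict:
        return {
            "set": self.set_label,
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auroc": self.auroc,
        }


@dataclass
class SplitPlan:
    """Per-record train/test assignment for one repetition.

    Per patient with n >= 2 records the training count is round(ratio * n)
    clamped to [1, n-1]; single-record patients go to training (their random
    effect must be estimable for scoring).
    """

    train_mask: np.ndarray
    repetition: int
    seed: int


def default_ladder(outcome: Outcome) -> list[DetectionModelSpec]:
    """Simple-to-complex candidate sequence for the dominance walk."""
    if outcome == "dep":
        seqs = [
            ("depnsp_t",),
            ("depnsp_t",),
            ("depnsp_t", "depnsp_t-1"),
            ("depnsp_t", "depnsp_t-1", "depnsp_t-2"),
        ]
    else:
        seqs = [("man_t",), ("man_t",), ("man_t", "man_t-1")]
    ladder = [DetectionModelSpec(outcome, seqs[0], random_structure="none")]
    ladder += [
        DetectionModelSpec(outcome, terms, random_structure="intercept")
        for terms in seqs[1:]
    ]
    return ladder


def build_feature_table(
    records: pd.DataFrame, spec: DetectionModelSpec
) -> pd.DataFrame:
    """Feature rows (label, terms, patient_id) for one model spec.

    Rows missing a lag the spec requires are dropped (complete case); the
    drop count is logged.  The original row index is preserved so shared
    split plans can be applied across specs.
    """
    cols = [TERM_COLUMNS[t] for t in spec.terms]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"records lack required column(s): {', '.join(missing)}")
    out = records[["patient_id", _LABEL_COLUMN[spec.outcome], *cols]].copy()
    out = out.rename(columns={_LABEL_COLUMN[spec.outcome]: "label"})
    complete = out[cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d rows lacking required lag values", spec.label, n_dropped
        )
    out = out.loc[complete]
    if out.empty:
        raise ValueError(f"no complete-case rows for spec {spec.label}")
    out["label"] = out["label"].astype(int)
    return out


def fit_logistic_mixed(
    rows: pd.DataFrame, spec: DetectionModelSpec
) -> LogisticMixedClassifier:
    """Fit the Laplace logistic mixed model for one spec."""
    feature_cols = [TERM_COLUMNS[t] for t in spec.terms]
    X = rows[feature_cols].to_numpy(dtype=float)
    y = rows["label"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both relapse and nonrelapse rows are required for fitting")
    clf = LogisticMixedClassifier(random_structure=spec.random_structure)
    clf.fit(X, y, groups=rows["patient_id"].to_numpy())
    return clf


def predict_prob(
    model: LogisticMixedClassifier, rows: pd.DataFrame, spec: DetectionModelSpec
) -> np.ndarray:
    """Relapse probabilities; unseen patients score with zero random effect."""
    feature_cols = [TERM_COLUMNS[t] for t in spec.terms]
    X = rows[feature_cols].to_numpy(dtype=float)
    return model.predict_proba(X, groups=rows["patient_id"].to_numpy())[:, 1]


def calibrate_threshold(
    train_probs: np.ndarray,
    train_labels: np.ndarray,
    target_specificity: float = 0.90,
) -> float:
    """Smallest threshold achieving the target training specificity.

    Candidates are midpoints of adjacent distinct sorted negative-class
    probabilities plus sentinels below and above all of them; the prediction
    rule is "relapse iff prob >= t" (ties at t count as positive), so
    specificity counts negatives strictly below t.
    """
    train_probs = np.asarray(train_probs, dtype=float)
    train_labels = np.asarray(train_labels)
    neg = np.sort(train_probs[train_labels == 0])
    if len(neg) == 0:
        raise ValueError("threshold calibration needs at least one negative label")
    distinct = np.unique(neg)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(
        [[0.0], mids, [np.nextafter(distinct[-1], np.inf)]]
    )
    n_neg = len(neg)
    for t in candidates:
        specificity = np.sum(neg < t) / n_neg
        if specificity >= target_specificity:
            return float(t)
    return float(candidates[-1])  # unreachable: the last sentinel always attains 1


def _auroc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUROC with half credit for ties."""
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(probs)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(
    probs: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    set_label: str = "test",
) -> DetectionMetrics:
    """Confusion counts at the threshold plus rank-statistic AUROC."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels length mismatch")
    pred = probs >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    auroc = _auroc(probs, labels)
    return DetectionMetrics(
        set_label=set_label,
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        auroc=auroc,
        auroc_defined=not np.isnan(auroc),
    )


def make_split_plan(
    patient_ids: np.ndarray,
    ratio: float,
    rng: np.random.Generator,
    repetition: int = 0,
    seed: int = 0,
) -> SplitPlan:
    """Grouped proportional split: each patient is represented by the same
    ratio of their records in training and testing."""
    n = len(patient_ids)
    train = np.zeros(n, dtype=bool)
    for pid in np.unique(patient_ids):
        rows = np.flatnonzero(patient_ids == pid)
        ni = len(rows)
        if ni == 1:
            train[rows] = True
            continue
        k = int(np.floor(ratio * ni + 0.5))
        k = min(max(k, 1), ni - 1)
        chosen = rng.choice(rows, size=k, replace=False)
        train[chosen] = True
    return SplitPlan(train_mask=train, repetition=repetition, seed=seed)


def _run_one_split(
    rows: pd.DataFrame,
    spec: DetectionModelSpec,
    train_mask: np.ndarray,
    target_specificity: float,
) -> tuple[DetectionMetrics, DetectionMetrics]:
    train = rows.loc[train_mask]
    test = rows.loc[~train_mask]
    model = fit_logistic_mixed(train, spec)
    p_train = predict_prob(model, train, spec)
    t = calibrate_threshold(
        p_train, train["label"].to_numpy(), target_specificity
    )
    m_train = evaluate(p_train, train["label"].to_numpy(), t, set_label="train")
    p_test = predict_prob(model, test, spec)
    m_test = evaluate(p_test, test["label"].to_numpy(), t, set_label="test")
    return m_train, m_test


def repeated_split_validation(
    rows: pd.DataFrame,
    spec: DetectionModelSpec,
    ratio: float = 0.7,
    reps: int = 999,
    target_specificity: float = 0.90,
    seed: int = 0,
    max_redraws: int = 10,
) -> pd.DataFrame:
    """Repeated grouped holdout: split, fit, calibrate, evaluate, ``reps`` times.

    Returns one row per repetition and set (train/test) with the four
    performance metrics, the threshold and the confusion counts.  Splits
    whose training set lacks a class are redrawn (at most ``max_redraws``
    times, then counted as failed).
    """
    rng = np.random.default_rng(seed)
    pids = rows["patient_id"].to_numpy()
    labels = rows["label"].to_numpy()
    out = []
    for rep in range(reps):
        plan = None
        for _ in range(max_redraws + 1):
            cand = make_split_plan(pids, ratio, rng, repetition=rep, seed=seed)
            tr = labels[cand.train_mask]
            te = labels[~cand.train_mask]
            if tr.min() < tr.max() and len(te) > 0:
                plan = cand
                break
        if plan is None:
            logger.warning("repetition %d: no usable split after redraws", rep)
            out.append({"repetition": rep, "failed": True})
            continue
        try:
            m_train, m_test = _run_one_split(
                rows, spec, plan.train_mask, target_specificity
            )
        except (ValueError, ConvergenceError) as exc:
            logger.warning("repetition %d failed: %s", rep, exc)
            out.append({"repetition": rep, "failed": True})
            continue
        for m in (m_train, m_test):
            out.append({"repetition": rep, "failed": False, **m.as_dict()})
    return pd.DataFrame(out)


def summarize_metrics(results: pd.DataFrame) -> dict:
    """Mean and central 95% interval of each metric per set."""
    summary: dict = {"n_failed": int(results.get("failed", pd.Series()).sum())}
    ok = results[~results["failed"]] if "failed" in results else results
    for set_label in ("train", "test"):
        sub = ok[ok["set"] == set_label]
        block = {}
        for metric in ("accuracy", "sensitivity", "specificity", "auroc"):
            vals = sub[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            lo, hi = np.percentile(vals, [2.5, 97.5])
            block[metric] = {
                "mean": float(vals.mean()),
                "p2.5": float(lo),
                "p97.5": float(hi),
            }
        summary[set_label] = block
    return summary


def model_selection_ladder(
    records: pd.DataFrame,
    ladder: Sequence[DetectionModelSpec],
    reps: int = 999,
    ratio: float = 0.7,
    target_specificity: float = 0.90,
    seed: int = 0,
    win_threshold: float = 0.90,
) -> tuple[DetectionModelSpec, pd.DataFrame]:
    """Pairwise dominance walk over an ordered simple-to-complex ladder.

    Both models of each pair run on shared split plans built over the full
    record set (each model then keeps its complete-case rows).  The complex
    model is adopted only if its test AUROC strictly exceeds the simpler
    model's in at least ``win_threshold`` of the repetitions; ties count as
    "not better".
    """
    ladder = list(ladder)
    if not ladder:
        raise ValueError("ladder must contain at least one spec")
    best = ladder[0]
    pair_rows = []
    for challenger in ladder[1:]:
        rng = np.random.default_rng(seed)
        rows_best = build_feature_table(records, best)
        rows_chal = build_feature_table(records, challenger)
        pids = records["patient_id"].to_numpy()
        wins = 0
        valid = 0
        n_failed = 0
        for rep in range(reps):
            plan = make_split_plan(pids, ratio, rng, repetition=rep, seed=seed)
            mask = pd.Series(plan.train_mask, index=records.index)
            try:
                _, m_best = _run_one_split(
                    rows_best,
                    best,
                    mask.loc[rows_best.index].to_numpy(),
                    target_specificity,
                )
                _, m_chal = _run_one_split(
                    rows_chal,
                    challenger,
                    mask.loc[rows_chal.index].to_numpy(),
                    target_specificity,
                )
            except (ValueError, ConvergenceError) as exc:
                n_failed += 1
                logger.warning(
                    "pair (%s vs %s) repetition %d failed: %s",
                    best.label,
                    challenger.label,
                    rep,
                    exc,
                )
                continue
            if np.isnan(m_best.auroc) or np.isnan(m_chal.auroc):
                n_failed += 1
                continue
            valid += 1
            wins += m_chal.auroc > m_best.auroc
        win_fraction = wins / valid if valid else float("nan")
        adopted = valid > 0 and win_fraction >= win_threshold
        pair_rows.append(
            {
                "simple": best.label,
                "complex": challenger.label,
                "win_fraction": win_fraction,
                "n_valid": valid,
                "n_failed": n_failed,
                "adopted": adopted,
            }
        )
        if adopted:
            best = challenger
    return best, pd.DataFrame(pair_rows)
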