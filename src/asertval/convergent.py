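"""Convergent validity of self-report subscores against clinician scales.

Three tools:

* :func:`fit_lme` — Gaussian linear mixed model (REML) of a clinician total
  on a self-report subscore, with patient-level random intercept and slope
  (falling back to simpler random structures on non-convergence).
* :func:`weighted_group_correlation` — the two-step pooled correlation:
  per-patient Pearson r, then a weighted mean with weights proportional to
  each patient's number of observations.
* :func:`case_bootstrap` — two-level case bootstrap: resample patients with
  replacement, then observations within each drawn patient; patients drawn
  multiply become distinct clusters.  The two-sided p-value is the
  sign-crossing rule with +1 smoothing, the CI the percentile interval.

Inference for the headline coefficients comes from the case bootstrap; no
Wald or Satterthwaite machinery is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .mixed import (
    HAVE_NUMBA,
    ConvergenceError,
    LinearMixedRegressor,
    _STRUCTURE_CODE,
    _reml_d2_kernel,
)

__all__ = [
    "LmeFit",
    "WeightedCorrelation",
    "BootstrapResult",
    "fit_lme",
    "weighted_group_correlation",
    "item_pair_correlations",
    "case_bootstrap",
    "bootstrap_lme_slope",
    "ITEM_PAIRS",
]

logger = logging.getLogger(__name__)

# Fixed item pairings between the questionnaire and the clinician scales:
# (label, clinician item column, questionnaire item column).
ITEM_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("MADRS2_sadness~A1_sadness", "m2", "q1"),
    ("MADRS9_pessimism~A4_future", "m9", "q4"),
    ("YMRS2_energy~A6_energy", "y2", "q6"),
    ("YMRS7_speech_thought~A7_acceleration", "y7", "q7"),
    ("YMRS4_sleep~A8_sleep", "y4", "q8"),
    ("MADRS3_tension~A9_unrest", "m3", "q9"),
    ("MADRS6_concentration~A10_concentration", "m6", "q10"),
)


@dataclass
class LmeFit:
    """Fixed and random-effect estimates of one convergent-validity model."""

    response: str
    predictor: str
    intercept: float
    slope: float
    re_intercept_var: float
    re_slope_var: float
    re_cov: float
    resid_var: float
    structure: str
    converged: bool
    n_obs: int
    n_patients: int
    random_effects: dict = field(default_factory=dict, repr=False)
    theta: Optional[tuple[float, ...]] = field(default=None, repr=False)
    p_slope: Optional[float] = None
    slope_ci: Optional[tuple[float, float]] = None


@dataclass
class WeightedCorrelation:
    """Weighted two-step group correlation."""

    x: str
    y: str
    estimate: float
    per_patient: pd.DataFrame  # patient_id, r, n, weight
    n_excluded: int
    p_value: Optional[float] = None


@dataclass
class BootstrapResult:
    estimate: float
    resamples: np.ndarray
    p_value: float
    ci_low: float
    ci_high: float
    n_failed: int
    seed: int


def fit_lme(
    records: pd.DataFrame,
    response: str = "madrs_total",
    predictor: str = "depnsp_sum",
    random_structure: str = "full",
    theta_init: Optional[Sequence[float]] = None,
) -> LmeFit:
    """REML fit of ``response ~ predictor`` with patient random intercept+slope.

    Requires at least two patients with two or more records each.
    """
    x = records[predictor].to_numpy(dtype=float)
    y = records[response].to_numpy(dtype=float)
    groups = records["patient_id"].to_numpy()
    est = LinearMixedRegressor(
        random_structure=random_structure, theta_init=theta_init
    ).fit(x, y, groups=groups)
    D = est.re_cov_
    q = D.shape[0]
    return LmeFit(
        response=response,
        predictor=predictor,
        intercept=est.intercept_,
        slope=float(est.coef_[0]),
        re_intercept_var=float(D[0, 0]),
        re_slope_var=float(D[1, 1]) if q > 1 else 0.0,
        re_cov=float(D[0, 1]) if q > 1 else 0.0,
        resid_var=est.resid_var_,
        structure=est.structure_,
        converged=est.converged_,
        n_obs=len(y),
        n_patients=est.n_groups_,
        random_effects={k: v.tolist() for k, v in est.random_effects_.items()},
        theta=tuple(float(t) for t in est.theta_)
        if est.structure_ == random_structure
        else None,
    )


def weighted_group_correlation(
    records: pd.DataFrame,
    x: str,
    y: str,
    min_obs: int = 3,
) -> WeightedCorrelation:
    """Two-step correlation: per-patient Pearson r, then an n-weighted mean.

    Patients with fewer than ``min_obs`` records or zero variance in either
    variable are excluded and counted, never silently dropped.
    """
    rows = []
    n_excluded = 0
    for pid, sub in records.groupby("patient_id", sort=True):
        xv = sub[x].to_numpy(dtype=float)
        yv = sub[y].to_numpy(dtype=float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        xv, yv = xv[ok], yv[ok]
        if len(xv) < min_obs or xv.std() == 0.0 or yv.std() == 0.0:
            n_excluded += 1
            continue
        r = float(np.corrcoef(xv, yv)[0, 1])
        rows.append({"patient_id": pid, "r": r, "n": len(xv)})
    if not rows:
        raise ValueError(
            f"no patient with >= {min_obs} records and nonzero variance "
            f"in both {x} and {y}"
        )
    per = pd.DataFrame(rows)
    per["weight"] = per["n"] / per["n"].sum()
    estimate = float((per["weight"] * per["r"]).sum())
    return WeightedCorrelation(
        x=x, y=y, estimate=estimate, per_patient=per, n_excluded=n_excluded
    )


def item_pair_correlations(
    records: pd.DataFrame, min_obs: int = 3
) -> dict[str, WeightedCorrelation]:
    """Weighted group correlations for the seven fixed clinician/self-report
    item pairs.  Pairs whose item-level columns are absent are skipped with a
    notice."""
    out: dict[str, WeightedCorrelation] = {}
    for label, clin_col, q_col in ITEM_PAIRS:
        if clin_col not in records.columns:
            logger.warning(
                "item-level column %s absent; skipping pair %s", clin_col, label
            )
            continue
        try:
            out[label] = weighted_group_correlation(
                records, x=q_col, y=clin_col, min_obs=min_obs
            )
        except ValueError as exc:
            logger.warning("pair %s skipped: %s", label, exc)
    return out


def _summarize_resamples(estimate, values, n_failed, seed) -> BootstrapResult:
    ok = np.isfinite(values)
    vals = values[ok]
    n_ok = len(vals)
    p_low = (1 + np.sum(vals <= 0.0)) / (n_ok + 1)
    p_high = (1 + np.sum(vals >= 0.0)) / (n_ok + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapResult(
        estimate=float(estimate),
        resamples=values,
        p_value=float(p),
        ci_low=float(lo),
        ci_high=float(hi),
        n_failed=int(n_failed),
        seed=seed,
    )


def _gls_slope_core(theta, code, a, b, c, p, r):
    """Profiled GLS slope at a given random-effect Cholesky (d = 2).

    ``code``: 0 = intercept-only, 1 = full, 2 = diagonal (as in the REML
    kernel); jitted when numba is available.
    """
    if code == 0:
        l0 = theta[0]
        K = 1.0 + l0 * l0 * a
        g = l0 * l0 / K
        sxx00 = np.sum(a - g * a * a)
        sxx01 = np.sum(b - g * a * b)
        sxx11 = np.sum(c - g * b * b)
        sxy0 = np.sum(p - g * a * p)
        sxy1 = np.sum(r - g * b * p)
    else:
        if code == 1:
            l0, l1, l2 = theta[0], theta[1], theta[2]
        else:
            l0, l2 = theta[0], theta[1]
            l1 = 0.0
        K11 = 1.0 + l0 * l0 * a + 2.0 * l0 * l1 * b + l1 * l1 * c
        K12 = l2 * (l0 * b + l1 * c)
        K22 = 1.0 + l2 * l2 * c
        det = K11 * K22 - K12 * K12
        U11 = l0 * a + l1 * b
        U12 = l0 * b + l1 * c
        U21 = l2 * b
        U22 = l2 * c
        u1 = l0 * p + l1 * r
        u2 = l2 * r
        W11 = (K22 * U11 - K12 * U21) / det
        W12 = (K22 * U12 - K12 * U22) / det
        W21 = (-K12 * U11 + K11 * U21) / det
        W22 = (-K12 * U12 + K11 * U22) / det
        w1 = (K22 * u1 - K12 * u2) / det
        w2 = (-K12 * u1 + K11 * u2) / det
        sxx00 = np.sum(a - (U11 * W11 + U21 * W21))
        sxx01 = np.sum(b - (U11 * W12 + U21 * W22))
        sxx11 = np.sum(c - (U12 * W12 + U22 * W22))
        sxy0 = np.sum(p - (U11 * w1 + U21 * w2))
        sxy1 = np.sum(r - (U12 * w1 + U22 * w2))
    detS = sxx00 * sxx11 - sxx01 * sxx01
    return (-sxx01 * sxy0 + sxx00 * sxy1) / detS


def _nm_reml(theta0, code, a, b, c, p, r, t, n):
    """Nelder-Mead minimisation of the profiled REML criterion.

    Self-contained so the whole bootstrap loop can run inside numba; the
    slope is insensitive to the last digits of theta, so a moderate
    tolerance suffices.
    """
    k = theta0.shape[0]
    sim = np.empty((k + 1, k))
    fvals = np.empty(k + 1)
    for i in range(k + 1):
        for j in range(k):
            sim[i, j] = theta0[j]
        if i > 0:
            sim[i, i - 1] += 0.15 * abs(theta0[i - 1]) + 0.05
        fvals[i] = _reml_d2_kernel(sim[i], code, a, b, c, p, r, t, n)
    for _ in range(400):
        order = np.argsort(fvals)
        sim = sim[order]
        fvals = fvals[order]
        if fvals[k] - fvals[0] < 1e-9 * (1.0 + abs(fvals[0])):
            break
        cent = np.zeros(k)
        for i in range(k):
            cent += sim[i]
        cent /= k
        xr = cent + (cent - sim[k])
        fr = _reml_d2_kernel(xr, code, a, b, c, p, r, t, n)
        if fr < fvals[0]:
            xe = cent + 2.0 * (cent - sim[k])
            fe = _reml_d2_kernel(xe, code, a, b, c, p, r, t, n)
            if fe < fr:
                sim[k] = xe
                fvals[k] = fe
            else:
                sim[k] = xr
                fvals[k] = fr
        elif fr < fvals[k - 1]:
            sim[k] = xr
            fvals[k] = fr
        else:
            xc = cent + 0.5 * (sim[k] - cent)
            fc = _reml_d2_kernel(xc, code, a, b, c, p, r, t, n)
            if fc < fvals[k]:
                sim[k] = xc
                fvals[k] = fc
            else:
                for i in range(1, k + 1):
                    sim[i] = sim[0] + 0.5 * (sim[i] - sim[0])
                    fvals[i] = _reml_d2_kernel(sim[i], code, a, b, c, p, r, t, n)
    best = np.argmin(fvals)
    return sim[best]


def _lme_boot_loop(W, starts, lens, B, seed, code, theta0):
    """Case-bootstrap loop over per-cluster sufficient statistics.

    Draws clusters with replacement, then rows within each drawn cluster,
    rebuilds the cluster Gram sums, re-optimises the REML criterion from
    the full-data optimum and records the GLS slope.  Jitted when numba is
    available; seeded through numba's (or numpy's) legacy global RNG.
    """
    np.random.seed(seed)
    m = starts.shape[0]
    slopes = np.empty(B)
    sa = np.empty(m)
    sb = np.empty(m)
    sc = np.empty(m)
    sp = np.empty(m)
    sr = np.empty(m)
    for bi in range(B):
        t_total = 0.0
        n_total = 0
        for k in range(m):
            i = np.random.randint(0, m)
            st = starts[i]
            ln = lens[i]
            vb = 0.0
            vc = 0.0
            vp = 0.0
            vr = 0.0
            for _ in range(ln):
                rr = st + np.random.randint(0, ln)
                x = W[rr, 1]
                y = W[rr, 2]
                vb += x
                vc += x * x
                vp += y
                vr += x * y
                t_total += y * y
            sa[k] = ln
            sb[k] = vb
            sc[k] = vc
            sp[k] = vp
            sr[k] = vr
            n_total += ln
        theta = _nm_reml(theta0, code, sa, sb, sc, sp, sr, t_total, n_total)
        slopes[bi] = _gls_slope_core(theta, code, sa, sb, sc, sp, sr)
    return slopes


if HAVE_NUMBA:
    from numba import njit as _njit

    _gls_slope_core = _njit(cache=True)(_gls_slope_core)
    _nm_reml = _njit(cache=True)(_nm_reml)
    _lme_boot_loop = _njit(cache=True)(_lme_boot_loop)


def bootstrap_lme_slope(
    records: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
    response: str = "madrs_total",
    predictor: str = "depnsp_sum",
    random_structure: str = "full",
) -> BootstrapResult:
    """Two-level case bootstrap of the REML LME slope, refitted per resample.

    Statistically equivalent to ``case_bootstrap`` with an LME-slope
    statistic, but works at the level of per-cluster sufficient statistics:
    each resample draws patients with replacement, then rows within each
    drawn patient, rebuilds the cluster Gram sums and re-optimises the
    profiled REML criterion (warm-started from the full-data optimum).
    With numba present the entire loop runs compiled, so ten thousand
    refits take seconds.  Intended for the single-predictor model; other
    statistics go through :func:`case_bootstrap`.
    """
    est0 = fit_lme(
        records,
        response=response,
        predictor=predictor,
        random_structure=random_structure,
    )
    theta0 = np.asarray(
        est0.theta
        if est0.theta is not None
        else ([1.0, 0.0, 1.0] if random_structure == "full" else [1.0, 1.0]),
        dtype=np.float64,
    )
    structure = est0.structure if est0.theta is not None else random_structure
    code = _STRUCTURE_CODE[structure]

    x = records[predictor].to_numpy(dtype=float)
    y = records[response].to_numpy(dtype=float)
    pids = records["patient_id"].to_numpy()
    unique_pids, inverse = np.unique(pids, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    W = np.ascontiguousarray(
        np.column_stack([np.ones_like(x), x, y])[order]
    )
    lens = np.bincount(inverse).astype(np.int64)
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]]).astype(np.int64)

    values = _lme_boot_loop(W, starts, lens, int(B), int(seed) % (2**31), code, theta0)
    n_failed = int(np.sum(~np.isfinite(values)))
    if n_failed > 0.10 * B:
        raise RuntimeError(
            f"LME slope bootstrap aborted: {n_failed}/{B} refits failed"
        )
    return _summarize_resamples(est0.slope, values, n_failed, seed)


def case_bootstrap(
    statistic: Callable[[pd.DataFrame], float],
    records: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
    max_failure_rate: float = 0.10,
) -> BootstrapResult:
    """Two-level case bootstrap of a statistic over (patients, observations).

    Each resample draws patients with replacement, then rows with replacement
    within each drawn patient; a patient drawn twice contributes two distinct
    clusters (fresh ids).  Returns the sign-crossing two-sided p-value with
    +1 smoothing and the percentile 95% CI.  Aborts if more than
    ``max_failure_rate`` of resample statistics fail.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    estimate = float(statistic(records))

    pids = records["patient_id"].to_numpy()
    unique_pids, inverse = np.unique(pids, return_inverse=True)
    m = len(unique_pids)
    row_idx_by_patient = [np.flatnonzero(inverse == i) for i in range(m)]

    values = np.empty(B)
    n_failed = 0
    patient_col = records.columns.get_loc("patient_id")
    for b in range(B):
        drawn = rng.integers(0, m, size=m)
        idx_parts = []
        labels_parts = []
        for k, i in enumerate(drawn):
            rows = row_idx_by_patient[i]
            take = rows[rng.integers(0, len(rows), size=len(rows))]
            idx_parts.append(take)
            labels_parts.append(np.full(len(rows), f"c{k}"))
        idx = np.concatenate(idx_parts)
        resampled = records.iloc[idx].copy()
        resampled.iloc[:, patient_col] = np.concatenate(labels_parts)
        try:
            values[b] = float(statistic(resampled))
        except (ValueError, ConvergenceError) as exc:
            values[b] = np.nan
            n_failed += 1
            if n_failed > max_failure_rate * B:
                raise RuntimeError(
                    f"case bootstrap aborted: {n_failed}/{b + 1} resample "
                    f"statistics failed (last error: {exc})"
                ) from exc
    return _summarize_resamples(estimate, values, n_failed, seed)
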