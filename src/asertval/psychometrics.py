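"""Internal-structure analysis: PCA of the 10 items, Cronbach alpha, response rate.

The PCA is an eigen-decomposition of the sample covariance matrix of the raw
0-4 item scores (not the correlation matrix): the published component SDs sum
in squares to about 3.77, far from the value 10 a correlation-matrix PCA of
ten items would give, so raw-covariance PCA is the analysis this module
reproduces.  Components are ordered by decreasing SD and the sign of each
loading column is fixed so that its largest-magnitude entry is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .domain import DEP_ITEMS, MAN_ITEMS, NSP_ITEMS, Patient

__all__ = [
    "PcaResult",
    "ReliabilityResult",
    "pca_items",
    "cronbach_alpha",
    "factor_alphas",
    "FACTOR_ITEM_GROUPS",
    "response_rate",
    "response_rate_summary",
]

logger = logging.getLogger(__name__)

# Fixed questionnaire item groups (0-based indices).
FACTOR_ITEM_GROUPS: dict[str, tuple[int, ...]] = {
    "dep": DEP_ITEMS,
    "man": MAN_ITEMS,
    "nsp": NSP_ITEMS,
    "depnsp": DEP_ITEMS + NSP_ITEMS,
    "mannsp": MAN_ITEMS + NSP_ITEMS,
}


@dataclass
class PcaResult:
    """Principal components of the item covariance matrix.

    ``loadings`` holds one orthonormal column per component (pc_1 ... pc_10);
    ``sds`` are the component standard deviations (sqrt eigenvalues);
    ``proportions`` are sds^2 / sum(sds^2).
    """

    loadings: np.ndarray  # (n_items, n_items)
    sds: np.ndarray
    proportions: np.ndarray
    cumulative: np.ndarray
    zero_variance_items: tuple[int, ...] = ()


@dataclass
class ReliabilityResult:
    label: str
    alpha: float
    n_items: int
    n_observations: int


def pca_items(responses: Sequence[Sequence[float]] | np.ndarray) -> PcaResult:
    """PCA of an (n x k) item matrix via the sample covariance eigenproblem.

    Requires n >= k + 1 complete rows.  Zero-variance items are reported in
    the result (the decomposition still runs).
    """
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2:
        raise ValueError("responses must be a 2-D item matrix")
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} rows for a {k}-item PCA, got {n}")
    variances = X.var(axis=0, ddof=1)
    zero_var = tuple(int(i) for i in np.flatnonzero(variances == 0.0))
    if zero_var:
        logger.warning("zero-variance item(s) at 0-based index %s", zero_var)
    cov = np.cov(X, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # Sign convention: largest-|loading| entry of each column is positive.
    for j in range(k):
        idx = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[idx, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    total = eigvals.sum()
    proportions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PcaResult(
        loadings=eigvecs,
        sds=np.sqrt(eigvals),
        proportions=proportions,
        cumulative=np.cumsum(proportions),
        zero_variance_items=zero_var,
    )


def cronbach_alpha(
    responses: Sequence[Sequence[float]] | np.ndarray, label: str = ""
) -> ReliabilityResult:
    """Cronbach alpha: k/(k-1) * (1 - sum(var_item) / var(total)).

    Sample variances use the n-1 denominator.  Requires k >= 2 items and
    n >= 3 observations; zero total variance is an error.
    """
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2:
        raise ValueError("responses must be a 2-D item matrix")
    n, k = X.shape
    if k < 2:
        raise ValueError("Cronbach alpha needs at least 2 items")
    if n < 3:
        raise ValueError("Cronbach alpha needs at least 3 observations")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise ValueError("zero total-score variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1.0 - item_var / total_var)
    return ReliabilityResult(label=label, alpha=float(alpha), n_items=k, n_observations=n)


def factor_alphas(
    responses: Sequence[Sequence[float]] | np.ndarray,
) -> dict[str, ReliabilityResult]:
    """Alphas for the fixed item groups: depressive (Q1-4), manic (Q5-8),
    nonspecific (Q9-10), and the combined depressive+nonspecific and
    manic+nonspecific sets."""
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2 or X.shape[1] != 10:
        raise ValueError("expected an (n x 10) item matrix")
    return {
        label: cronbach_alpha(X[:, list(idx)], label=label)
        for label, idx in FACTOR_ITEM_GROUPS.items()
    }


def response_rate(patient: Patient, n_filled: int) -> float:
    """Filled reports divided by weeks in study; deliberately not capped at 1."""
    if n_filled < 0:
        raise ValueError("n_filled must be nonnegative")
    return n_filled / patient.weeks_in_study


def response_rate_summary(
    patients: Sequence[Patient], filled_counts: dict[str, int]
) -> dict[str, float]:
    """Cohort mean and SD (ddof=1) of the per-patient response rates."""
    rates = np.array(
        [response_rate(p, filled_counts.get(p.patient_id, 0)) for p in patients]
    )
    return {
        "mean": float(rates.mean()),
        "sd": float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
        "n_patients": len(rates),
    }
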