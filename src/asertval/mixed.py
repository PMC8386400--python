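"""Mixed-effects model cores, written as scikit-learn style estimators.

Two estimators live here:

* :class:`LinearMixedRegressor` — Gaussian linear mixed model
  ``y = X b + Z u_i + e`` with patient-level random intercept (and optionally
  random slopes with full or diagonal covariance), fitted by restricted
  maximum likelihood (REML).  The implementation profiles the fixed effects
  and residual variance out of the REML criterion and evaluates it from
  per-cluster sufficient statistics, so a fit costs a low-dimensional
  derivative-free optimisation over the scaled random-effect Cholesky factor
  only.  This keeps the two-level case bootstrap (tens of thousands of
  refits) tractable.
* :class:`LogisticMixedClassifier` — logistic mixed model
  ``logit P(y=1) = X b + Z u_i`` fitted by maximising the Laplace
  approximation of the marginal likelihood, with the per-cluster modes
  (empirical Bayes / BLUP analogues) retained for scoring held-out
  observations of seen patients.

Both estimators take cluster membership through a ``groups`` argument to
``fit``/``predict`` and expose fitted attributes with trailing underscores.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

__all__ = ["LinearMixedRegressor", "LogisticMixedClassifier", "ConvergenceError"]

logger = logging.getLogger(__name__)

_FALLBACK_ORDER = {"full": ("full", "diagonal", "intercept"),
                   "diagonal": ("diagonal", "intercept"),
                   "intercept": ("intercept",)}


class ConvergenceError(RuntimeError):
    """Raised when a mixed model fails to converge after all fallbacks."""


def _as_design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("X must be 1- or 2-dimensional")
    n = X.shape[0]
    return np.hstack([np.ones((n, 1)), X])


def _group_index(groups: Sequence) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    labels, inverse = np.unique(groups, return_inverse=True)
    return labels, inverse


def _suffstats(W: np.ndarray, inverse: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster Gram matrices sum_j w_j w_j^T and cluster sizes."""
    c = W.shape[1]
    M = np.zeros((m, c, c))
    outer = W[:, :, None] * W[:, None, :]
    np.add.at(M, inverse, outer)
    counts = np.bincount(inverse, minlength=m).astype(float)
    return M, counts


def _build_L(theta: np.ndarray, q: int, structure: str) -> np.ndarray:
    L = np.zeros((q, q))
    if structure == "full":
        idx = np.tril_indices(q)
        L[idx] = theta
    else:  # diagonal / intercept
        L[np.diag_indices(q)] = theta
    return L


def _n_theta(q: int, structure: str) -> int:
    return q * (q + 1) // 2 if structure == "full" else q


def _sym_logdet(K: np.ndarray) -> float:
    """Sum of log-determinants of a stack of small SPD matrices."""
    q = K.shape[-1]
    if q == 1:
        d = K[:, 0, 0]
        return float(np.sum(np.log(d))) if np.all(d > 0) else np.inf
    if q == 2:
        det = K[:, 0, 0] * K[:, 1, 1] - K[:, 0, 1] * K[:, 1, 0]
        return float(np.sum(np.log(det))) if np.all(det > 0) else np.inf
    sign, ld = np.linalg.slogdet(K)
    return float(np.sum(ld)) if np.all(sign > 0) else np.inf


def _sym_solve(K: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Batched solve K X = B for stacks of 1x1 / 2x2 SPD matrices."""
    q = K.shape[-1]
    if q == 1:
        return B / K[:, :, 0][..., None] if B.ndim == 3 else B / K[:, 0, 0][:, None]
    if q == 2:
        a, b, c = K[:, 0, 0], K[:, 0, 1], K[:, 1, 1]
        det = a * c - b * b
        out = np.empty_like(B)
        out[:, 0] = (c[:, None] * B[:, 0] - b[:, None] * B[:, 1]) / det[:, None]
        out[:, 1] = (-b[:, None] * B[:, 0] + a[:, None] * B[:, 1]) / det[:, None]
        return out
    return np.linalg.solve(K, B)


def _reml_d2_kernel(theta, code, a, b, c, p, r, t, n):
    """Profiled REML criterion for the one-predictor model (d = 2).

    ``code``: 0 = intercept-only, 1 = full Cholesky, 2 = diagonal.
    Compiled with numba when available; the expression is pure elementwise
    arithmetic over per-cluster sums, so the jitted version runs in
    microseconds and makes the case-bootstrap refits cheap.
    """
    if code == 0:
        l0 = theta[0]
        K = 1.0 + l0 * l0 * a
        if np.any(K <= 0):
            return np.inf
        logdetK = float(np.sum(np.log(K)))
        g = l0 * l0 / K
        sxx00 = np.sum(a - g * a * a)
        sxx01 = np.sum(b - g * a * b)
        sxx11 = np.sum(c - g * b * b)
        sxy0 = np.sum(p - g * a * p)
        sxy1 = np.sum(r - g * b * p)
        syy = t - float(np.sum(g * p * p))
    else:
        if code == 1:  # full
            l0, l1, l2 = theta[0], theta[1], theta[2]
        else:  # diagonal
            l0, l2 = theta[0], theta[1]
            l1 = 0.0
        K11 = 1.0 + l0 * l0 * a + 2.0 * l0 * l1 * b + l1 * l1 * c
        K12 = l2 * (l0 * b + l1 * c)
        K22 = 1.0 + l2 * l2 * c
        det = K11 * K22 - K12 * K12
        if np.any(det <= 0):
            return np.inf
        logdetK = float(np.sum(np.log(det)))
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
        syy = t - float(np.sum(u1 * w1 + u2 * w2))
    detS = sxx00 * sxx11 - sxx01 * sxx01
    if detS <= 0:
        return np.inf
    beta0 = (sxx11 * sxy0 - sxx01 * sxy1) / detS
    beta1 = (-sxx01 * sxy0 + sxx00 * sxy1) / detS
    rss = syy - (sxy0 * beta0 + sxy1 * beta1)
    if rss < 1e-300:
        rss = 1e-300
    sigma2 = rss / (n - 2)
    return logdetK + (n - 2) * np.log(sigma2) + np.log(detS)


try:  # compile the hot kernel; fall back to the pure-python version
    from numba import njit as _njit

    _reml_d2_kernel = _njit(cache=True, fastmath=False)(_reml_d2_kernel)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

_STRUCTURE_CODE = {"intercept": 0, "full": 1, "diagonal": 2}


def _profiled_reml_d2(theta, structure, stats, n):
    """Profiled REML criterion, specialised to the one-predictor model.

    Inputs are forced contiguous so the jitted kernel compiles exactly once
    per process.
    """
    a, b, c, p, r, t = stats
    cc = np.ascontiguousarray
    return _reml_d2_kernel(
        cc(theta, dtype=np.float64),
        _STRUCTURE_CODE[structure],
        cc(a, dtype=np.float64),
        cc(b, dtype=np.float64),
        cc(c, dtype=np.float64),
        cc(p, dtype=np.float64),
        cc(r, dtype=np.float64),
        float(t),
        int(n),
    )


class LinearMixedRegressor(RegressorMixin, BaseEstimator):
    """Gaussian linear mixed model with patient-level random effects (REML).

    Parameters
    ----------
    random_structure : {"full", "diagonal", "intercept"}
        Random-effect structure: random intercept + slopes with full
        covariance, with independent (diagonal) covariance, or random
        intercept only.  On convergence failure the fit falls back one step
        at a time towards "intercept" (each step logged); the structure
        actually used is stored in ``structure_``.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
    re_cov_ : ndarray — covariance matrix of the random effects (y units).
    resid_var_ : float — residual variance.
    random_effects_ : dict mapping group label to its BLUP vector.
    structure_ : str — random structure actually fitted.
    converged_ : bool
    """

    def __init__(
        self,
        random_structure: str = "full",
        max_iter: int = 2000,
        theta_init: Optional[Sequence[float]] = None,
    ):
        self.random_structure = random_structure
        self.max_iter = max_iter
        # Warm start for the scaled Cholesky parameters (used by the case
        # bootstrap, which refits thousands of perturbed datasets).
        self.theta_init = theta_init

    # -- REML machinery -----------------------------------------------------

    def _criterion_parts(self, theta, structure, M, d, q, n):
        """Profiled REML criterion and the profiled estimates at theta."""
        L = _build_L(theta, q, structure)
        A = M[:, :q, :q]                      # Z'Z  (random cols lead the design)
        ZX = M[:, :q, :d]                     # Z'X
        Zy = M[:, :q, d]                      # Z'y
        XX = M[:, :d, :d]
        Xy = M[:, :d, d]
        yy = M[:, d, d]

        K = np.eye(q)[None] + L.T @ A @ L     # I + L' Z'Z L, always PD
        logdetK = _sym_logdet(K)
        if not np.isfinite(logdetK):
            return np.inf, None
        U = np.einsum("ab,mbd->mad", L.T, ZX)
        u = np.einsum("ab,mb->ma", L.T, Zy)
        V1 = _sym_solve(K, U)
        v1 = _sym_solve(K, u[..., None])[..., 0]
        S_XX = XX.sum(axis=0) - np.einsum("mab,mac->bc", U, V1)
        S_Xy = Xy.sum(axis=0) - np.einsum("mab,ma->b", U, v1)
        S_yy = yy.sum() - np.einsum("ma,ma->", u, v1)

        beta = np.linalg.solve(S_XX, S_Xy)
        rss = max(S_yy - S_Xy @ beta, 1e-300)
        sigma2 = rss / (n - d)
        sign, logdetS = np.linalg.slogdet(S_XX)
        if sign <= 0:
            return np.inf, None
        crit = logdetK + (n - d) * np.log(sigma2) + logdetS
        return crit, (L, K, beta, sigma2, ZX, Zy)

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (cluster labels) are required")
        Xd = _as_design(X)
        y = np.asarray(y, dtype=float)
        n, d = Xd.shape
        if y.shape != (n,):
            raise ValueError("y length does not match X")
        labels, inverse = _group_index(groups)
        m = len(labels)
        counts = np.bincount(inverse, minlength=m)
        if m < 2 or np.sum(counts >= 2) < 2:
            raise ValueError(
                "random effects unidentifiable: need >= 2 clusters with >= 2 records"
            )
        if d > 1 and np.any(Xd[:, 1:].std(axis=0) == 0.0):
            raise ValueError("degenerate predictor with zero variance")

        W = np.hstack([Xd, y[:, None]])
        M, _ = _suffstats(W, inverse, m)

        if d == 2:
            stats = (
                M[:, 0, 0],
                M[:, 0, 1],
                M[:, 1, 1],
                M[:, 0, 2],
                M[:, 1, 2],
                float(M[:, 2, 2].sum()),
            )
        else:
            stats = None

        last_exc: Optional[Exception] = None
        for structure in _FALLBACK_ORDER[self.random_structure]:
            q = d if structure in ("full", "diagonal") else 1
            theta0 = (
                np.eye(q)[np.tril_indices(q)]
                if structure == "full"
                else np.ones(_n_theta(q, structure))
            )
            if (
                self.theta_init is not None
                and structure == self.random_structure
                and len(self.theta_init) == len(theta0)
            ):
                theta0 = np.asarray(self.theta_init, dtype=float)

            if stats is not None:
                def obj(th, structure=structure):
                    val = _profiled_reml_d2(th, structure, stats, n)
                    return val if np.isfinite(val) else 1e12
            else:
                def obj(th, structure=structure, q=q):
                    try:
                        val = self._criterion_parts(th, structure, M, d, q, n)[0]
                    except np.linalg.LinAlgError:
                        return 1e12
                    return val if np.isfinite(val) else 1e12
            try:
                res = optimize.minimize(
                    obj,
                    theta0,
                    method="L-BFGS-B",
                    options={"maxiter": self.max_iter},
                )
                crit, parts = self._criterion_parts(res.x, structure, M, d, q, n)
                if not (np.isfinite(crit) and parts is not None):
                    raise ConvergenceError(f"non-finite criterion for {structure}")
            except (ConvergenceError, np.linalg.LinAlgError) as exc:
                logger.warning("LME %s structure failed (%s); falling back", structure, exc)
                last_exc = exc
                continue
            if not res.success:
                logger.warning(
                    "LME %s structure did not converge (%s); falling back",
                    structure,
                    res.message,
                )
                last_exc = ConvergenceError(str(res.message))
                continue

            L, K, beta, sigma2, ZX, Zy = parts
            self.structure_ = structure
            self.theta_ = res.x.copy()
            self.converged_ = True
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
            self.resid_var_ = float(sigma2)
            self.re_cov_ = sigma2 * (L @ L.T)
            self.n_groups_ = m
            # BLUPs: u_i = L K^-1 L' (Z'y - Z'X beta)
            resid = Zy - np.einsum("mqd,d->mq", ZX, beta)
            inner = _sym_solve(
                K, np.einsum("ab,mb->ma", L.T, resid)[..., None]
            )[..., 0]
            modes = np.einsum("ab,mb->ma", L, inner)
            q_used = L.shape[0]
            self._re_q_ = q_used
            self.random_effects_ = {
                labels[i]: modes[i].copy() for i in range(m)
            }
            self.reml_criterion_ = float(crit)
            self.n_features_in_ = d - 1
            return self
        raise ConvergenceError(
            f"linear mixed model failed to converge after fallbacks: {last_exc}"
        )

    def predict(self, X, groups=None):
        Xd = _as_design(X)
        eta = Xd @ np.concatenate([[self.intercept_], self.coef_])
        if groups is not None:
            q = self._re_q_
            for j, g in enumerate(np.asarray(groups)):
                u = self.random_effects_.get(g)
                if u is not None:
                    eta[j] += float(Xd[j, :q] @ u)
        return eta


class LogisticMixedClassifier(ClassifierMixin, BaseEstimator):
    """Logistic mixed model fitted by Laplace-approximated marginal likelihood.

    Parameters
    ----------
    random_structure : {"none", "intercept", "slope"}
        "none" is a plain logistic regression; "intercept" adds a patient-level
        random intercept; "slope" adds random slopes on all features with an
        unstructured covariance.
    ridge : float
        Per-observation L2 penalty scale on the non-intercept fixed effects.
        When zero and the fit diverges (separation), the model automatically
        refits with a weak ridge (1e-4 per observation) and sets
        ``separation_``.

    Attributes
    ----------
    classes_, intercept_, coef_, re_cov_, random_effects_, converged_,
    separation_ : fitted state; ``random_effects_`` maps group labels to the
    posterior modes used when scoring those patients' held-out rows (unseen
    patients score with a zero random effect).
    """

    _AUTO_RIDGE = 1e-4

    def __init__(
        self,
        random_structure: str = "intercept",
        ridge: float = 0.0,
        max_iter: int = 200,
        inner_tol: float = 1e-9,
    ):
        self.random_structure = random_structure
        self.ridge = ridge
        self.max_iter = max_iter
        self.inner_tol = inner_tol

    # -- Laplace likelihood -------------------------------------------------

    def _inner_modes_q1(self, eta_fix, y, inverse, m, sigma2):
        """Vectorised Newton for the per-cluster scalar modes (random intercept)."""
        b = np.zeros(m)
        for _ in range(60):
            eta = eta_fix + b[inverse]
            mu = expit(eta)
            grad = np.bincount(inverse, weights=y - mu, minlength=m) - b / sigma2
            hess = np.bincount(inverse, weights=mu * (1 - mu), minlength=m) + 1.0 / sigma2
            b = b + grad / hess
            if np.max(np.abs(grad)) < self.inner_tol:
                break
        eta = eta_fix + b[inverse]
        f = float(np.sum(y * eta - np.logaddexp(0.0, eta))) - float(
            np.sum(b**2) / (2.0 * sigma2)
        )
        hess = np.bincount(
            inverse, weights=expit(eta) * (1 - expit(eta)), minlength=m
        ) + 1.0 / sigma2
        logdet_H = float(np.sum(np.log(hess)))
        return b, f, logdet_H

    def _inner_modes_qk(self, Xd, eta_fix, y, inverse, m, D):
        """Per-cluster Newton for vector-valued modes (random slopes)."""
        q = D.shape[0]
        Dinv = np.linalg.inv(D + 1e-10 * np.eye(q))
        Z = Xd[:, :q]
        modes = np.zeros((m, q))
        f_total = 0.0
        logdet_H = 0.0
        for i in range(m):
            rows = np.flatnonzero(inverse == i)
            Zi, yi, ei = Z[rows], y[rows], eta_fix[rows]
            b = np.zeros(q)
            for _ in range(60):
                eta = ei + Zi @ b
                mu = expit(eta)
                g = Zi.T @ (yi - mu) - Dinv @ b
                H = Zi.T @ ((mu * (1 - mu))[:, None] * Zi) + Dinv
                step = np.linalg.solve(H, g)
                b = b + step
                if np.max(np.abs(g)) < self.inner_tol:
                    break
            eta = ei + Zi @ b
            mu = expit(eta)
            f_total += float(np.sum(yi * eta - np.logaddexp(0.0, eta))) - 0.5 * float(
                b @ Dinv @ b
            )
            H = Zi.T @ ((mu * (1 - mu))[:, None] * Zi) + Dinv
            sign, ld = np.linalg.slogdet(H)
            logdet_H += float(ld)
            modes[i] = b
        return modes, f_total, logdet_H

    def _neg_loglik(self, params, Xd, y, inverse, m, structure, ridge):
        d = Xd.shape[1]
        beta = params[:d]
        eta_fix = Xd @ beta
        penalty = 0.5 * ridge * len(y) * float(np.sum(beta[1:] ** 2))
        if structure == "none":
            ll = float(np.sum(y * eta_fix - np.logaddexp(0.0, eta_fix)))
            return -(ll) + penalty
        if structure == "intercept":
            sigma2 = float(np.exp(2.0 * params[d]))
            _, f, logdet_H = self._inner_modes_q1(eta_fix, y, inverse, m, sigma2)
            ll = f - 0.5 * m * np.log(sigma2) - 0.5 * logdet_H
            return -ll + penalty
        # random slopes: params[d:] packs the lower Cholesky of D
        q = d
        L = _build_L(params[d:], q, "full")
        D = L @ L.T
        sign, logdet_D = np.linalg.slogdet(D + 1e-10 * np.eye(q))
        _, f, logdet_H = self._inner_modes_qk(Xd, eta_fix, y, inverse, m, D)
        ll = f - 0.5 * logdet_D - 0.5 * logdet_H
        return -ll + penalty

    def _optimize(self, Xd, y, inverse, m, structure, ridge):
        d = Xd.shape[1]
        if structure == "none":
            x0 = np.zeros(d)
        elif structure == "intercept":
            x0 = np.concatenate([np.zeros(d), [0.0]])  # log sigma = 0
        else:
            # Seed the random-slope fit from the intercept-only optimum: the
            # joint Laplace surface is flat in the slope variance near zero
            # and a cold start often stalls.
            warm = self._optimize(Xd, y, inverse, m, "intercept", ridge)
            beta_init = warm.x[:d]
            sd_init = float(np.exp(warm.x[d]))
            q = d
            L0 = np.zeros((q, q))
            L0[0, 0] = max(sd_init, 0.05)
            for j in range(1, q):
                L0[j, j] = 0.05
            x0 = np.concatenate([beta_init, L0[np.tril_indices(q)]])
        bounds = None
        if structure == "intercept":
            bounds = [(None, None)] * d + [(-6.0, 4.0)]
        elif structure == "slope":
            # Bound the Cholesky entries: under within-cluster separation the
            # Laplace surface is flat towards infinite random-effect variance.
            bounds = [(None, None)] * d + [(-5.0, 5.0)] * (len(x0) - d)
        res = optimize.minimize(
            self._neg_loglik,
            x0,
            args=(Xd, y, inverse, m, structure, ridge),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.max_iter},
        )
        return res

    def fit(self, X, y, groups=None):
        Xd = _as_design(X)
        y = np.asarray(y, dtype=float)
        n, d = Xd.shape
        classes = np.unique(y)
        if not np.all(np.isin(classes, [0.0, 1.0])) or len(classes) < 2:
            raise ValueError("y must contain both binary classes 0 and 1")
        structure = self.random_structure
        if structure not in ("none", "intercept", "slope"):
            raise ValueError(f"unknown random_structure {structure!r}")
        if structure == "none":
            labels, inverse, m = np.array([]), np.zeros(n, dtype=int), 0
        else:
            if groups is None:
                raise ValueError("groups are required for random-effect structures")
            labels, inverse = _group_index(groups)
            m = len(labels)
            if m < 2:
                raise ValueError("need >= 2 clusters for random effects")

        ridge = self.ridge
        res = self._optimize(Xd, y, inverse, m, structure, ridge)
        beta = res.x[:d]
        self.separation_ = False
        if (not np.all(np.isfinite(res.x))) or np.max(np.abs(beta)) > 25.0:
            logger.warning(
                "logistic mixed fit unstable (separation suspected); "
                "refitting with ridge %.0e",
                self._AUTO_RIDGE,
            )
            ridge = max(ridge, self._AUTO_RIDGE)
            res = self._optimize(Xd, y, inverse, m, structure, ridge)
            self.separation_ = True
        if not np.all(np.isfinite(res.x)):
            raise ConvergenceError("logistic mixed model failed to converge")

        beta = res.x[:d]
        self.classes_ = np.array([0, 1])
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.converged_ = bool(res.success)
        self.ridge_used_ = ridge
        self.n_features_in_ = d - 1
        eta_fix = Xd @ beta
        if structure == "none":
            self.re_cov_ = np.zeros((0, 0))
            self.random_effects_ = {}
            self._re_q_ = 0
        elif structure == "intercept":
            sigma2 = float(np.exp(2.0 * res.x[d]))
            modes, _, _ = self._inner_modes_q1(eta_fix, y, inverse, m, sigma2)
            self.re_cov_ = np.array([[sigma2]])
            self.random_effects_ = {labels[i]: np.array([modes[i]]) for i in range(m)}
            self._re_q_ = 1
        else:
            q = d
            L = _build_L(res.x[d:], q, "full")
            D = L @ L.T
            modes, _, _ = self._inner_modes_qk(Xd, eta_fix, y, inverse, m, D)
            self.re_cov_ = D
            self.random_effects_ = {labels[i]: modes[i].copy() for i in range(m)}
            self._re_q_ = q
        return self

    def decision_function(self, X, groups=None):
        Xd = _as_design(X)
        eta = Xd @ np.concatenate([[self.intercept_], self.coef_])
        q = self._re_q_
        if groups is not None and q > 0:
            for j, g in enumerate(np.asarray(groups)):
                u = self.random_effects_.get(g)
                if u is not None:
                    eta[j] += float(Xd[j, :q] @ u)
        return eta

    def predict_proba(self, X, groups=None):
        p = expit(self.decision_function(X, groups=groups))
        return np.column_stack([1.0 - p, p])

    def predict(self, X, groups=None):
        return (self.decision_function(X, groups=groups) >= 0.0).astype(int)
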