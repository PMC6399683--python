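"""Conditional-independence tests for a binary target.

Provides the building blocks used on every data block:

* :func:`fit_logistic` -- maximum-likelihood binary logistic regression via a
  custom Newton solver with an Armijo backtracking line search and a fallback
  chain (Newton -> fixed-Hessian conjugate direction -> gradient descent) for
  the cases where the observed Hessian is not invertible.
* :func:`lrt_log_pvalue` -- nested-model likelihood-ratio test of
  ``T _|_ X | S`` with statistic ``D = -2 (LL0 - LL1) ~ chi2(df)``.
* :func:`score_test_log_pvalue` -- the Lagrange-multiplier test used when the
  conditioning set is empty; no model fitting required.
* :func:`chi2_log_sf` -- the natural log of the chi-square upper-tail
  probability computed directly in log space, accurate far beyond the point
  where the p-value itself underflows (down to ``p ~ 1e-100000`` and below).

All p-values in this package live on the natural-log scale: selection
decisions on large samples routinely involve p-values far below the smallest
positive double, and a single p-value rounded to zero would poison the
downstream Fisher combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, log_ndtr

__all__ = [
    "LogisticModel",
    "LRTResult",
    "DegenerateFitError",
    "UndefinedTestError",
    "fit_logistic",
    "lrt_log_pvalue",
    "score_test_log_pvalue",
    "chi2_log_sf",
]

LN2 = float(np.log(2.0))


class DegenerateFitError(ValueError):
    """Target has a single class; no logistic MLE exists."""

    def __init__(self, klass: int):
        self.klass = int(klass)
        super().__init__(f"target contains a single class ({self.klass})")


class UndefinedTestError(ValueError):
    """Test statistic undefined (e.g. constant candidate in a score test)."""


# ---------------------------------------------------------------------------
# log-space chi-square survival function
# ---------------------------------------------------------------------------

def chi2_log_sf(x, df: int):
    """Natural log of the chi-square upper-tail probability ``P(X >= x)``.

    The tail is the regularized upper incomplete gamma function
    ``Q(df/2, x/2)``.  It is evaluated entirely in log space via the upward
    recurrence ``Q(a+1, z) = Q(a, z) + z^a e^(-z) / Gamma(a+1)`` starting
    from the closed forms ``Q(1/2, z) = erfc(sqrt(z))`` (via ``log_ndtr``)
    and ``Q(1, z) = e^(-z)``, so that p-values as small as ``1e-100000``
    retain full relative accuracy in the log.

    Parameters
    ----------
    x : float or array
        Statistic value(s), ``>= 0`` (``inf`` maps to ``-inf``).
    df : int
        Degrees of freedom, ``>= 1``.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("statistic must be non-negative")
    z = x / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        if df % 2 == 1:
            a = 0.5
            out = LN2 + log_ndtr(-np.sqrt(x))
        else:
            a = 1.0
            out = -z
        logz = np.log(z)
        while a < df / 2.0 - 1e-12:
            term = a * logz - z - gammaln(a + 1.0)
            out = np.logaddexp(out, term)
            a += 1.0
    out = np.where(np.isposinf(x), -np.inf, out)
    # never report log p > 0 from roundoff
    out = np.minimum(out, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Fitted binary logistic regression.

    ``coefficients`` holds the intercept first; ``n_params`` equals its
    length and is the model's degrees-of-freedom contribution to nested
    tests.  ``method_used`` records the deepest fallback level reached
    during fitting.
    """

    coefficients: np.ndarray
    log_likelihood: float
    n_params: int
    converged: bool
    method_used: str = "newton"
    iterations: int = 0


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum_i [ y_i eta_i - log(1 + exp(eta_i)) ], computed stably
    return float(np.dot(y, eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_logistic(
    design: np.ndarray,
    target: np.ndarray,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    ll_tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood fit of a binary logistic regression.

    ``design`` must already contain the intercept column.  The primary
    update is a Newton step; when the observed-information matrix cannot be
    factorized the step direction falls back to the fixed Hessian
    ``X'X / 4`` (a global curvature bound for the logistic likelihood, with
    a small ridge if needed) and, as a last resort, to plain gradient
    ascent.  Every step is guarded by Armijo backtracking, so the
    log-likelihood never decreases.  On perfectly separable data the fit
    stops at ``max_iter`` with ``converged=False`` rather than raising.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("design/target contain non-finite values")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateFitError(int(classes[0]))
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("target must be 0/1 coded")
    n, p = X.shape
    beta = np.zeros(p) if init is None else np.array(init, dtype=float)
    eta = X @ beta
    ll = _loglik(eta, y)
    method = "newton"
    converged = False
    it = 0
    fixed_hessian = None
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        direction = None
        try:
            H = (X.T * w) @ X
            # pivot floor: a Cholesky pivot below 1e-10 of the largest marks
            # the curvature matrix as effectively singular
            L = np.linalg.cholesky(H)
            piv = np.diagonal(L) ** 2
            if piv.min() < 1e-10 * piv.max():
                raise np.linalg.LinAlgError
            direction = np.linalg.solve(H, grad)
            if not np.all(np.isfinite(direction)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            # fixed-Hessian conjugate direction; ridge allowed only here
            method = "cg_fixed_hessian"
            try:
                if fixed_hessian is None:
                    fixed_hessian = (X.T @ X) / 4.0
                    fixed_hessian += 1e-8 * np.eye(p) * max(
                        1.0, np.trace(fixed_hessian) / p
                    )
                direction = np.linalg.solve(fixed_hessian, grad)
                if not np.all(np.isfinite(direction)):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                method = "gradient_descent"
                direction = grad
        # Armijo backtracking: ascent is guaranteed because direction'grad >= 0
        slope = float(grad @ direction)
        if slope < 0:  # non-ascent direction (numerical): fall back to gradient
            method = "gradient_descent"
            direction = grad
            slope = float(grad @ grad)
        step = 1.0
        accepted = False
        for _ in range(50):
            beta_new = beta + step * direction
            eta_new = X @ beta_new
            ll_new = _loglik(eta_new, y)
            if ll_new >= ll + 1e-4 * step * slope:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        delta = step * direction
        beta, eta = beta_new, eta_new
        ll_prev, ll = ll, ll_new
        # the coefficient-update test only counts on a full step: a step
        # crushed by backtracking says nothing about being at an optimum
        if (step == 1.0 and np.max(np.abs(delta)) < tol) or abs(
            ll - ll_prev
        ) <= ll_tol * max(1.0, abs(ll_prev)):
            converged = True
            break
    # perfect separation: the likelihood approaches its supremum of 0 with
    # ever-growing slopes -- no interior MLE exists, flag as not converged
    if ll > -1e-6 and np.max(np.abs(beta)) > 10.0:
        converged = False
    return LogisticModel(
        coefficients=beta,
        log_likelihood=ll,
        n_params=p,
        converged=converged,
        method_used=method,
        iterations=it,
    )


def _fit_logistic_many(
    base_design: np.ndarray,
    cand_columns: np.ndarray,
    target: np.ndarray,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    ll_tol: float = 1e-10,
    max_iter: int = 100,
):
    """Fit one alternative model per candidate column, vectorized.

    ``base_design`` is the shared ``(n, p0)`` null design (intercept and
    selected features); ``cand_columns`` is ``(n, ncand)``.  Returns
    ``(coefs (ncand, p0+1), loglik (ncand,), converged (ncand,))``.  The
    batched path runs a masked Newton/Armijo iteration across candidates;
    any candidate that fails numerically is refit with the robust scalar
    :func:`fit_logistic`.
    """
    n, p0 = base_design.shape
    ncand = cand_columns.shape[1]
    p = p0 + 1
    y = np.asarray(target, dtype=float).ravel()
    X = np.empty((ncand, n, p))
    X[:, :, :p0] = base_design[None, :, :]
    X[:, :, p0] = cand_columns.T
    beta = np.zeros((ncand, p))
    if init is not None:
        beta[:, :p0] = np.asarray(init, dtype=float)[None, :]
    eta = np.einsum("cnp,cp->cn", X, beta)
    ll = eta @ y - np.sum(np.logaddexp(0.0, eta), axis=1)
    active = np.ones(ncand, dtype=bool)
    converged = np.zeros(ncand, dtype=bool)
    failed = np.zeros(ncand, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Xa = X[idx]
        mu = expit(eta[idx])
        grad = np.einsum("cnp,cn->cp", Xa, y[None, :] - mu)
        w = mu * (1.0 - mu)
        H = np.einsum("cnp,cn,cnq->cpq", Xa, w, Xa)
        try:
            direction = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            failed[idx] = True
            active[idx] = False
            break
        bad = ~np.all(np.isfinite(direction), axis=1)
        if bad.any():
            failed[idx[bad]] = True
            active[idx[bad]] = False
            keep = ~bad
            idx, Xa, grad, direction = idx[keep], Xa[keep], grad[keep], direction[keep]
            if idx.size == 0:
                continue
        slope = np.einsum("cp,cp->c", grad, direction)
        neg = slope < 0
        if neg.any():  # fall back to gradient direction for those candidates
            direction[neg] = grad[neg]
            slope[neg] = np.einsum("cp,cp->c", grad[neg], grad[neg])
        step = np.ones(idx.size)
        need = np.ones(idx.size, dtype=bool)
        beta_new = np.empty_like(direction)
        eta_new = np.empty((idx.size, n))
        ll_new = np.empty(idx.size)
        for _bt in range(50):
            sub = np.flatnonzero(need)
            if sub.size == 0:
                break
            beta_new[sub] = beta[idx[sub]] + step[sub, None] * direction[sub]
            eta_new[sub] = np.einsum("cnp,cp->cn", Xa[sub], beta_new[sub])
            ll_new[sub] = eta_new[sub] @ y - np.sum(
                np.logaddexp(0.0, eta_new[sub]), axis=1
            )
            ok = ll_new[sub] >= ll[idx[sub]] + 1e-4 * step[sub] * slope[sub]
            need[sub[ok]] = False
            step[sub[~ok]] *= 0.5
        stalled = need  # no acceptable step found
        failed[idx[stalled]] = failed[idx[stalled]] | ~np.isfinite(ll_new[stalled])
        active[idx[stalled]] = False
        good = ~need
        gi = idx[good]
        delta = step[good, None] * direction[good]
        ll_prev = ll[gi].copy()
        beta[gi] = beta_new[good]
        eta[gi] = eta_new[good]
        ll[gi] = ll_new[good]
        done = ((step[good] == 1.0) & (np.max(np.abs(delta), axis=1) < tol)) | (
            np.abs(ll[gi] - ll_prev) <= ll_tol * np.maximum(1.0, np.abs(ll_prev))
        )
        converged[gi[done]] = True
        active[gi[done]] = False
    # robust scalar refit for anything the batch could not handle
    redo = failed | (~converged & ~np.all(np.isfinite(beta), axis=1))
    redo |= ~np.isfinite(ll)
    for c in np.flatnonzero(redo):
        m = fit_logistic(
            X[c], y, init=None, tol=tol, ll_tol=ll_tol, max_iter=max_iter
        )
        beta[c] = m.coefficients
        ll[c] = m.log_likelihood
        converged[c] = m.converged
    return beta, ll, converged


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    """Likelihood-ratio test outcome for ``T _|_ X | S``."""

    statistic: float
    df: int
    log_pvalue: float
    null_model: LogisticModel
    alt_log_likelihood: float


#: negative statistics larger than this (in magnitude) trigger a warning
_NEG_STAT_TOL = 1e-6


def _as_2d(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    return v


def lrt_log_pvalue(
    target,
    cond_values,
    cand_values,
    null_model: LogisticModel | None = None,
) -> LRTResult:
    """Likelihood-ratio test of ``T _|_ X | S`` via nested logistic fits.

    ``cond_values`` holds the columns of the conditioning set ``S`` (may be
    ``None`` or empty for a marginal test); ``cand_values`` is a vector for
    a continuous/binary candidate or an ``(n, K-1)`` dummy matrix for a
    K-level categorical one (``df = K - 1``).  A previously fitted null
    model for the same rows and conditioning set may be passed to avoid
    refitting it per candidate.  Small negative statistics from numerical
    noise are clipped to zero.
    """
    y = np.asarray(target, dtype=float).ravel()
    n = y.size
    if cond_values is None:
        S = np.empty((n, 0))
    else:
        S = _as_2d(cond_values)
    Xc = _as_2d(cand_values)
    df = Xc.shape[1]
    base = np.column_stack([np.ones(n), S])
    if null_model is None:
        null_model = fit_logistic(base, y)
    init = np.append(null_model.coefficients, np.zeros(df))
    alt = fit_logistic(np.column_stack([base, Xc]), y, init=init)
    D = -2.0 * (null_model.log_likelihood - alt.log_likelihood)
    if D < -_NEG_STAT_TOL:
        import warnings

        warnings.warn(
            f"likelihood-ratio statistic {D:.3e} is negative beyond tolerance; "
            "alternative fit may not have converged",
            stacklevel=2,
        )
    D = max(D, 0.0)
    return LRTResult(
        statistic=D,
        df=df,
        log_pvalue=chi2_log_sf(D, df),
        null_model=null_model,
        alt_log_likelihood=alt.log_likelihood,
    )


def score_statistic(target, cand_values) -> float:
    """Univariate score (Lagrange multiplier) statistic for a binary target.

    ``z = sum_j X_j (T_j - Tbar) / sqrt(Tbar (1 - Tbar) sum_j (X_j - Xbar)^2)``.
    """
    y = np.asarray(target, dtype=float).ravel()
    x = np.asarray(cand_values, dtype=float).ravel()
    tbar = y.mean()
    if tbar <= 0.0 or tbar >= 1.0:
        raise DegenerateFitError(int(round(tbar)))
    ssx = np.sum((x - x.mean()) ** 2)
    if ssx <= 0.0:
        raise UndefinedTestError("constant candidate column: score test undefined")
    return float(np.dot(x, y - tbar) / np.sqrt(tbar * (1.0 - tbar) * ssx))


def score_test_log_pvalue(target, cand_values) -> float:
    """Two-sided log p-value of the univariate score test (standard-normal null).

    Equivalent to ``chi2_log_sf(z**2, 1)``; used only when the conditioning
    set is empty.
    """
    z = score_statistic(target, cand_values)
    return float(LN2 + log_ndtr(-abs(z)))


def score_test_log_pvalues_many(target, cand_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized univariate score tests over the columns of ``cand_matrix``.

    Returns ``(log_pvalues, statistics)``.  Constant columns yield a log
    p-value of 0 (statistic 0): on a single block a flat column carries no
    evidence against independence.
    """
    y = np.asarray(target, dtype=float).ravel()
    X = np.asarray(cand_matrix, dtype=float)
    tbar = y.mean()
    if tbar <= 0.0 or tbar >= 1.0:
        raise DegenerateFitError(int(round(tbar)))
    centered = X - X.mean(axis=0, keepdims=True)
    ssx = np.sum(centered**2, axis=0)
    num = X.T @ (y - tbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / np.sqrt(tbar * (1.0 - tbar) * ssx)
    z = np.where(ssx > 0.0, z, 0.0)
    logp = LN2 + log_ndtr(-np.abs(z))
    return logp, z
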