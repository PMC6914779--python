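"""Penalized logistic regression by IRLS coordinate descent (numba kernels).

Objective, for outcome y in {0, 1}, linear predictor eta = b0 + X beta::

    (1/n) * sum_i log(1 + exp(-s_i * eta_i))
        + sum_j l1[j] * |beta_j|  +  0.5 * sum_j l2[j] * beta_j**2

with s_i = 2 y_i - 1 and an unpenalized intercept.  Per-coefficient
penalty vectors cover both stages of the selection procedure: ridge
(l1 = 0, l2 = lambda) and adaptive LASSO (l1 = lambda * w_j, l2 = 0).

The solver is the standard glmnet-style scheme: an outer iteratively
reweighted least-squares (IRLS) loop builds a quadratic approximation of
the deviance at the current eta; an inner cyclic coordinate-descent loop
solves the penalized weighted least-squares problem with soft-threshold
updates, cycling over the active (nonzero) set between full
KKT-verification passes.  Cyclic order and pure floating-point updates
make the solver fully deterministic; soft thresholding produces exact
zeros, so "selected" is literally beta_j != 0.

Leave-one-out machinery never copies the design: a fold is fit by zeroing
the working weight of the left-out row (``skip``), warm-started from the
full-data solution at the same penalty.  Cross-validation fold fits use a
relaxed tolerance (they only feed the CV deviance, a sum over n held-out
log-losses); full-data and jackknife fits use the tight tolerance because
their exact zero patterns are the result.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WEIGHT_CAP = 1e8  # adaptive-weight cap guarding 1/|beta| for tiny ridge coefficients
_W_FLOOR = 1e-6  # IRLS working-weight floor
_MU_CLIP = 1e-9

MAX_OUTER = 60
MAX_INNER = 1000
TOL = 1e-7  # full-data / jackknife fits
CV_TOL = 1e-4  # cross-validation fold fits


@njit(cache=False)
def _cd_fit(X, y, l1, l2, beta, intercept, max_outer, max_inner, tol, skip):
    """In-place CD fit, ignoring row ``skip`` (pass -1 to use all rows).

    Returns (intercept, converged_flag).
    """
    n, p = X.shape
    n_eff = n - 1 if 0 <= skip < n else n
    eta = intercept + X @ beta
    active = np.empty(p, dtype=np.int64)
    converged = False
    for _ in range(max_outer):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.empty(n)
        z = np.empty(n)
        for i in range(n):
            if i == skip:
                w[i] = 0.0
                z[i] = eta[i]
                continue
            m = mu[i]
            if m < _MU_CLIP:
                m = _MU_CLIP
            elif m > 1.0 - _MU_CLIP:
                m = 1.0 - _MU_CLIP
            wi = m * (1.0 - m)
            if wi < _W_FLOOR:
                wi = _W_FLOOR
            w[i] = wi
            z[i] = eta[i] + (y[i] - m) / wi
        r = z - eta
        wsum = w.sum()
        need_full = True
        n_active = 0
        for _ in range(max_inner):
            max_delta = 0.0
            d0 = np.dot(w, r) / wsum
            intercept += d0
            for i in range(n):
                r[i] -= d0
            if abs(d0) > max_delta:
                max_delta = abs(d0)
            if need_full:
                n_active = 0
                for j in range(p):
                    vj = 0.0
                    rho = 0.0
                    for i in range(n):
                        wx = w[i] * X[i, j]
                        vj += wx * X[i, j]
                        rho += wx * r[i]
                    vj /= n_eff
                    if vj > 0.0:
                        rho = rho / n_eff + vj * beta[j]
                        if rho > l1[j]:
                            bnew = (rho - l1[j]) / (vj + l2[j])
                        elif rho < -l1[j]:
                            bnew = (rho + l1[j]) / (vj + l2[j])
                        else:
                            bnew = 0.0
                        d = bnew - beta[j]
                        if d != 0.0:
                            beta[j] = bnew
                            for i in range(n):
                                r[i] -= d * X[i, j]
                            if abs(d) > max_delta:
                                max_delta = abs(d)
                    if beta[j] != 0.0:
                        active[n_active] = j
                        n_active += 1
                if max_delta < tol:
                    break  # KKT verified on every coordinate
                need_full = False
            else:
                for a in range(n_active):
                    j = active[a]
                    vj = 0.0
                    rho = 0.0
                    for i in range(n):
                        wx = w[i] * X[i, j]
                        vj += wx * X[i, j]
                        rho += wx * r[i]
                    vj /= n_eff
                    if vj <= 0.0:
                        continue
                    rho = rho / n_eff + vj * beta[j]
                    if rho > l1[j]:
                        bnew = (rho - l1[j]) / (vj + l2[j])
                    elif rho < -l1[j]:
                        bnew = (rho + l1[j]) / (vj + l2[j])
                    else:
                        bnew = 0.0
                    d = bnew - beta[j]
                    if d != 0.0:
                        beta[j] = bnew
                        for i in range(n):
                            r[i] -= d * X[i, j]
                        if abs(d) > max_delta:
                            max_delta = abs(d)
                if max_delta < tol:
                    need_full = True  # converged on active set: verify KKT
        eta_new = z - r
        diff = 0.0
        for i in range(n):
            if i != skip and abs(eta_new[i] - eta[i]) > diff:
                diff = abs(eta_new[i] - eta[i])
        eta = eta_new
        if diff < tol:
            converged = True
            break
    return intercept, converged


@njit(cache=False)
def _deviance_one(eta, y):
    mu = 1.0 / (1.0 + np.exp(-eta))
    if mu < _MU_CLIP:
        mu = _MU_CLIP
    elif mu > 1.0 - _MU_CLIP:
        mu = 1.0 - _MU_CLIP
    return -2.0 * (y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu))


@njit(cache=False)
def _loo_path(X, y, l1_base, l2_base, lambdas, l1_scaled,
              max_outer, max_inner, tol, cv_tol):
    """LOO-CV deviance along a descending lambda path.

    ``l1_scaled`` selects whether lambda multiplies the l1 vector
    (adaptive-LASSO path) or the l2 vector (ridge path).  Returns
    (cv deviance per lambda, full-data betas, full-data intercepts).
    """
    n, p = X.shape
    n_lam = lambdas.size
    cv = np.zeros(n_lam)
    betas = np.zeros((n_lam, p))
    intercepts = np.zeros(n_lam)

    beta_full = np.zeros(p)
    b0_full = 0.0
    l1 = l1_base.copy()
    l2 = l2_base.copy()
    for k in range(n_lam):
        lam = lambdas[k]
        if l1_scaled:
            for j in range(p):
                l1[j] = l1_base[j] * lam
        else:
            for j in range(p):
                l2[j] = l2_base[j] * lam
        b0_full, _ = _cd_fit(X, y, l1, l2, beta_full, b0_full,
                             max_outer, max_inner, tol, -1)
        betas[k] = beta_full
        intercepts[k] = b0_full
        dev = 0.0
        for i in range(n):
            beta_i = beta_full.copy()
            b0_i, _ = _cd_fit(X, y, l1, l2, beta_i, b0_full,
                              max_outer, max_inner, cv_tol, i)
            eta_i = b0_i + np.dot(X[i], beta_i)
            dev += _deviance_one(eta_i, y[i])
        cv[k] = dev
    return cv, betas, intercepts


@njit(cache=False)
def _jackknife(X, y, l1, l2, beta_start, b0_start, max_outer, max_inner, tol):
    """Leave-one-out refits at fixed penalties; returns (selection counts, n_failed)."""
    n, p = X.shape
    counts = np.zeros(p)
    n_failed = 0
    for i in range(n):
        beta_i = beta_start.copy()
        _, ok = _cd_fit(X, y, l1, l2, beta_i, b0_start,
                        max_outer, max_inner, tol, i)
        if not ok:
            n_failed += 1
        for j in range(p):
            if beta_i[j] != 0.0:
                counts[j] += 1.0
    return counts, n_failed


# ---------------------------------------------------------------------------
# python-level wrappers
# ---------------------------------------------------------------------------

def fit_penalized_logistic(X, y, l1, l2, beta0=None, intercept0=0.0, tol=TOL):
    """Single penalized logistic fit; returns (beta, intercept, converged)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=np.float64).copy()
    l1 = np.broadcast_to(np.asarray(l1, dtype=np.float64), (p,)).copy()
    l2 = np.broadcast_to(np.asarray(l2, dtype=np.float64), (p,)).copy()
    intercept, ok = _cd_fit(X, y, l1, l2, beta, float(intercept0),
                            MAX_OUTER, MAX_INNER, tol, -1)
    return beta, intercept, bool(ok)


def loo_tuned_path(X, y, lambdas, l1_weights=None, ridge=False, tol=TOL, cv_tol=CV_TOL):
    """LOO-CV over a descending lambda grid.

    Returns a dict with the per-lambda CV deviance, the index of the
    selected lambda (minimum deviance; ties resolve to the largest
    lambda), and the full-data coefficients at every lambda.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    p = X.shape[1]
    if ridge:
        l1_base = np.zeros(p)
        l2_base = np.ones(p)
    else:
        l1_base = np.broadcast_to(
            np.ones(p) if l1_weights is None else np.asarray(l1_weights, dtype=np.float64),
            (p,),
        ).copy()
        l2_base = np.zeros(p)
    cv, betas, intercepts = _loo_path(
        X, y, l1_base, l2_base, lambdas, not ridge,
        MAX_OUTER, MAX_INNER, tol, cv_tol,
    )
    best = int(np.argmin(cv))  # grid is descending: first minimum = largest lambda
    return {
        "cv_deviance": cv,
        "best_index": best,
        "lambda": float(lambdas[best]),
        "betas": betas,
        "intercepts": intercepts,
    }


def jackknife_counts(X, y, l1, l2, beta_start, intercept_start, tol=TOL):
    """Selection counts over n leave-one-out refits at fixed penalties."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    p = X.shape[1]
    l1 = np.broadcast_to(np.asarray(l1, dtype=np.float64), (p,)).copy()
    l2 = np.broadcast_to(np.asarray(l2, dtype=np.float64), (p,)).copy()
    counts, n_failed = _jackknife(
        X, y, l1, l2,
        np.asarray(beta_start, dtype=np.float64),
        float(intercept_start),
        MAX_OUTER, MAX_INNER, tol,
    )
    return counts, int(n_failed)
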