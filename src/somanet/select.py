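"""Ridge-weighted adaptive-LASSO signature selection with jackknife stability.

The selection procedure, run on the modulated analytes:

1. **Design** — log2-transform the normalized RFUs, z-score each analyte
   column, encode the outcome as 1 = case (cardiovascular death).
2. **Ridge stage** — penalized logistic regression with a quadratic
   penalty; the penalty strength is tuned by leave-one-out (LOO)
   cross-validated binomial deviance.  The adaptive weights are the
   inverted absolute ridge coefficients, w_j = 1 / |beta_j| (capped at
   1e8: ridge coefficients are almost surely nonzero, the cap only guards
   numerics).
3. **Adaptive LASSO** — L1 penalty lambda * w_j per coefficient, lambda
   again tuned by LOO deviance; selected variables are the nonzero
   coefficients of the full-data fit.
4. **Jackknife stability** — with lambda, weights and standardization
   frozen from the full-data fits, the adaptive LASSO is refit n times,
   each time leaving one sample out.  The selection frequency of an
   analyte is the fraction of refits selecting it; the final signature
   keeps analytes with frequency strictly above 0.90.

Lambda grids are 100 log-spaced values descending from lambda_max (the
smallest penalty that zeroes every coefficient, for the LASSO stage) down
to 1e-4 * lambda_max; ties in CV deviance resolve to the larger lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _solvers
from ._solvers import WEIGHT_CAP
from .containers import RFUMatrix

FREQUENCY_THRESHOLD = 0.90
N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-4


@dataclass
class DesignMatrix:
    """Standardized log2 design for the penalized regressions."""

    X: np.ndarray  # n × p, columns mean 0 / SD 1
    y: np.ndarray  # 1 = case
    analytes: list
    sample_ids: list
    column_means: np.ndarray
    column_sds: np.ndarray
    dropped: list = field(default_factory=list)  # zero-variance columns


@dataclass
class SelectionResult:
    """Full record of the selection procedure."""

    lambda_ridge: float
    ridge_coefs: pd.Series
    weights: pd.Series
    lambda_alasso: float
    alasso_coefs: pd.Series
    full_fit_selected: list
    frequency: pd.Series
    signature: list
    n_jackknife: int
    n_failed: int

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ridge_coef": self.ridge_coefs,
                "weight": self.weights,
                "alasso_coef": self.alasso_coefs,
                "full_fit_selected": self.alasso_coefs != 0.0,
                "frequency": self.frequency,
                "in_signature": self.frequency.index.isin(self.signature),
            }
        )


def prepare_design(
    matrix: RFUMatrix, modulated, samples: pd.DataFrame, group_col: str = "group"
) -> DesignMatrix:
    """Restrict to modulated analytes, log2-transform, z-score columns.

    Columns are ordered by analyte id so that the procedure is invariant
    to the order in which the modulated set is supplied; zero-variance
    columns are dropped with a warning.
    """
    analytes = sorted(modulated)
    missing = [a for a in analytes if a not in matrix.values.columns]
    if missing:
        raise ValueError(f"modulated analytes absent from matrix: {missing[:5]}")
    common = matrix.samples.intersection(samples.index)
    X = np.log2(matrix.values.loc[common, analytes].to_numpy(dtype=float))
    y = (samples.loc[common, group_col] == "case").to_numpy(dtype=float)

    means = X.mean(axis=0)
    sds = X.std(axis=0)
    keep = sds > 0
    dropped = [a for a, k in zip(analytes, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance analytes: {dropped[:5]}")
    X = (X[:, keep] - means[keep]) / sds[keep]
    return DesignMatrix(
        X=np.ascontiguousarray(X),
        y=y,
        analytes=[a for a, k in zip(analytes, keep) if k],
        sample_ids=list(common),
        column_means=means[keep],
        column_sds=sds[keep],
        dropped=dropped,
    )


def _score_scale(X, y):
    """max_j |x_j'(y - ybar)| / n — anchor for the lambda grids."""
    resid = y - y.mean()
    return float(np.max(np.abs(X.T @ resid)) / X.shape[0]) if X.size else 0.0


def default_ridge_grid(design: DesignMatrix, n_lambda: int = N_LAMBDA):
    """Descending ridge grid spanning strong to weak shrinkage."""
    anchor = _score_scale(design.X, design.y)
    if anchor <= 0:
        anchor = 1.0
    return np.geomspace(100.0 * anchor, LAMBDA_MIN_RATIO * anchor, n_lambda)


def ridge_weights(design: DesignMatrix, lambda_grid=None):
    """Ridge stage: LOO-tuned quadratic penalty, inverted-coefficient weights.

    Returns ``(lambda_ridge, ridge_coefs, weights)`` with coefficients and
    weights as Series indexed by analyte.
    """
    if design.X.shape[0] < 10:
        raise ValueError("ridge stage needs at least 10 samples")
    if lambda_grid is None:
        lambda_grid = default_ridge_grid(design)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    path = _solvers.loo_tuned_path(design.X, design.y, lambda_grid, ridge=True)
    k = path["best_index"]
    coefs = pd.Series(path["betas"][k], index=design.analytes)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.abs(coefs.to_numpy())
    weights = pd.Series(np.minimum(w, WEIGHT_CAP), index=design.analytes)
    weights[~np.isfinite(weights)] = WEIGHT_CAP
    return float(path["lambda"]), coefs, weights


def default_alasso_grid(design: DesignMatrix, weights, n_lambda: int = N_LAMBDA):
    """Descending grid from lambda_max (all-zero fit) down to 1e-4·lambda_max."""
    w = np.asarray(weights, dtype=float)
    resid = design.y - design.y.mean()
    scores = np.abs(design.X.T @ resid) / design.X.shape[0]
    effective = scores / w  # columns at the weight cap cannot set the scale
    lam_max = float(np.max(effective))
    if lam_max <= 0:
        return None
    return np.geomspace(lam_max, LAMBDA_MIN_RATIO * lam_max, n_lambda)


def adaptive_lasso(design: DesignMatrix, weights, lambda_grid=None):
    """Adaptive-LASSO stage at LOO-tuned lambda.

    Returns ``(lambda_alasso, selected, coefs, intercept)``; ``selected``
    is the list of analytes with nonzero full-data coefficients.
    """
    w = pd.Series(weights).reindex(design.analytes).to_numpy(dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("adaptive weights must be positive and finite")
    if np.all(w >= WEIGHT_CAP):
        warnings.warn("all adaptive weights at cap: empty selection")
        zeros = pd.Series(0.0, index=design.analytes)
        return float("inf"), [], zeros, float(np.log(design.y.mean() / (1 - design.y.mean())))
    if lambda_grid is None:
        lambda_grid = default_alasso_grid(design, w)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    path = _solvers.loo_tuned_path(design.X, design.y, lambda_grid, l1_weights=w)
    k = path["best_index"]
    coefs = pd.Series(path["betas"][k], index=design.analytes)
    selected = list(coefs.index[coefs != 0.0])
    return float(path["lambda"]), selected, coefs, float(path["intercepts"][k])


def jackknife_frequencies(
    design: DesignMatrix, weights, lambda_alasso: float, start_coefs=None,
    start_intercept: float = 0.0,
):
    """Leave-one-out selection frequencies at frozen lambda and weights.

    Each of the n refits drops one sample from the (already standardized)
    design; frequency_j = (#refits with nonzero beta_j) / n.  Refits that
    hit the iteration cap are counted as failures but keep the
    denominator at n.
    """
    w = pd.Series(weights).reindex(design.analytes).to_numpy(dtype=float)
    n = design.X.shape[0]
    beta0 = (
        np.zeros(len(design.analytes))
        if start_coefs is None
        else pd.Series(start_coefs).reindex(design.analytes).to_numpy(dtype=float)
    )
    counts, n_failed = _solvers.jackknife_counts(
        design.X, design.y, lambda_alasso * w, np.zeros_like(w), beta0, start_intercept
    )
    if n_failed:
        warnings.warn(f"{n_failed} jackknife refits hit the iteration cap")
    return pd.Series(counts / n, index=design.analytes), n_failed


def final_signature(frequency, threshold: float = FREQUENCY_THRESHOLD):
    """Analytes with selection frequency strictly above the threshold."""
    freq = pd.Series(frequency, dtype=float)
    if len(freq) == 0:
        return []
    if ((freq < 0) | (freq > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    return list(freq.index[freq > threshold])


def run_selection(
    design: DesignMatrix,
    ridge_grid=None,
    alasso_grid=None,
    threshold: float = FREQUENCY_THRESHOLD,
) -> SelectionResult:
    """Full procedure: ridge → weights → adaptive LASSO → jackknife → signature."""
    lam_r, coefs_r, weights = ridge_weights(design, lambda_grid=ridge_grid)
    lam_a, selected, coefs_a, b0 = adaptive_lasso(design, weights, lambda_grid=alasso_grid)
    if not np.isfinite(lam_a):
        freq = pd.Series(0.0, index=design.analytes)
        n_failed = 0
    else:
        freq, n_failed = jackknife_frequencies(
            design, weights, lam_a, start_coefs=coefs_a, start_intercept=b0
        )
    return SelectionResult(
        lambda_ridge=lam_r,
        ridge_coefs=coefs_r,
        weights=weights,
        lambda_alasso=lam_a,
        alasso_coefs=coefs_a,
        full_fit_selected=selected,
        frequency=freq,
        signature=final_signature(freq, threshold=threshold),
        n_jackknife=design.X.shape[0],
        n_failed=n_failed,
    )
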