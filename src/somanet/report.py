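"""Reporting helpers: heat-map matrix, clinical correlations, cross-platform checks."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .containers import RFUMatrix
from .diff import wilcoxon_test


def heatmap_matrix(matrix: RFUMatrix, signature, samples: pd.DataFrame,
                   group_col: str = "group"):
    """Row-standardized signature × sample matrix for heat-map display.

    Columns are the samples in two fixed blocks — controls first, then
    cases, original within-group order preserved (groups are fixed, not
    clustered).  Rows are the signature analytes ordered by average-linkage
    hierarchical clustering of their z-score profiles (Euclidean distance).

    Returns ``(Z, annotations)``: the ordered z-score DataFrame (rows =
    analytes, columns = samples) and the clinical annotation table in the
    same column order — or ``None`` for an empty signature.
    """
    signature = list(signature)
    if not signature:
        warnings.warn("empty signature: nothing to draw")
        return None
    common = matrix.samples.intersection(samples.index)
    groups = samples.loc[common, group_col]
    col_order = list(common[groups != "case"]) + list(common[groups == "case"])

    values = matrix.values.loc[col_order, signature].to_numpy(dtype=float).T
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant analyte -> all-zero z-scores
    z = (values - mean) / sd

    if len(signature) > 2:
        order = list(leaves_list(average(pdist(z, metric="euclidean"))))
    elif len(signature) == 2:
        order = [0, 1]
    else:
        order = [0]
    zdf = pd.DataFrame(
        z[order], index=[signature[i] for i in order], columns=col_order
    )
    annotations = samples.loc[col_order]
    return zdf, annotations


def correlate_with_clinical(values, clinical):
    """Pearson correlation (r, two-sided p) with pairwise-complete handling."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(clinical, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired non-missing observations")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cross_platform_validation(platform_a, platform_b, groups):
    """Agreement of a protein across two measurement platforms.

    Pearson r between the platforms plus the two-group Wilcoxon test on
    platform B (case vs control).  Returns a dict with ``r``, ``r_p``,
    ``wilcoxon_p``.
    """
    a = np.asarray(platform_a, dtype=float)
    b = np.asarray(platform_b, dtype=float)
    groups = np.asarray(groups)
    if a.shape != b.shape or a.shape != groups.shape:
        raise ValueError("platforms and groups must cover the same samples")
    try:
        r, rp = correlate_with_clinical(a, b)
    except ValueError:
        r, rp = float("nan"), float("nan")
    _, wp = wilcoxon_test(b[groups == "case"], b[groups != "case"])
    return {"r": r, "r_p": rp, "wilcoxon_p": wp}
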