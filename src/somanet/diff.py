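"""Per-analyte two-group screening and cohort summary statistics.

The screen is the classic unadjusted case/control protocol for omics
panels: a Mann-Whitney-Wilcoxon rank test per analyte, Benjamini-Hochberg
FDR adjustment across analytes, and a fold-change gate.  An analyte is
called *modulated* when ``p_adj < alpha`` and ``|log2FC| > lfc`` (both
strict; defaults alpha = 0.05, lfc = 0.25).  Fold change is the ratio of
raw-scale group means (case / control), reported as mean ± SEM per group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import RFUMatrix

ALPHA = 0.05
LFC = 0.25

#: exact Wilcoxon enumeration is used when both groups are at most this size
#: and the pooled values are tie-free; otherwise the normal approximation
#: with tie-corrected variance and continuity correction.
EXACT_MAX_N = 8


def _check_group(x, name):
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError(f"{name} group is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} group contains non-finite values")
    return x


def wilcoxon_test(case, control):
    """Two-sided Mann-Whitney-Wilcoxon test.

    Returns ``(W, p)`` where ``W`` is the rank sum of the case group.
    Exact enumeration when both groups have <= 8 observations and the
    pooled sample is tie-free; tie-corrected normal approximation with
    continuity correction otherwise.
    """
    case = _check_group(case, "case")
    control = _check_group(control, "control")
    pooled = np.concatenate([case, control])
    tie_free = np.unique(pooled).size == pooled.size
    if case.size <= EXACT_MAX_N and control.size <= EXACT_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(case, control, alternative="two-sided", method=method)
    w = float(res.statistic) + case.size * (case.size + 1) / 2.0
    return w, float(res.pvalue)


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(case, control):
    """Case/control ratio of means with per-group mean ± SEM.

    Returns a dict with keys ``fc``, ``log2fc``, ``case_mean``,
    ``control_mean``, ``case_sem``, ``control_sem``.
    """
    case = _check_group(case, "case")
    control = _check_group(control, "control")
    cm, gm = float(np.mean(case)), float(np.mean(control))
    if cm <= 0 or gm <= 0:
        raise ValueError("group means must be > 0 for a fold change")
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return {
        "fc": cm / gm,
        "log2fc": float(np.log2(cm / gm)),
        "case_mean": cm,
        "control_mean": gm,
        "case_sem": sem(case),
        "control_sem": sem(control),
    }


def differential_table(
    matrix: RFUMatrix, samples: pd.DataFrame, group_col: str = "group",
    alpha: float = ALPHA, lfc: float = LFC,
) -> pd.DataFrame:
    """Per-analyte screening table over the plasma analytes of a matrix.

    Hybridization controls are not tested.  Large groups are tested with
    the vectorized asymptotic Wilcoxon; small tie-free groups fall back to
    the exact test analyte by analyte.
    """
    common = matrix.samples.intersection(samples.index)
    groups = samples.loc[common, group_col]
    case_ids = common[groups == "case"]
    control_ids = common[groups == "control"]
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise ValueError("both groups must be non-empty")

    analytes = matrix.assay_analytes
    case = matrix.values.loc[case_ids, analytes].to_numpy(dtype=float)
    control = matrix.values.loc[control_ids, analytes].to_numpy(dtype=float)

    if case.shape[0] > EXACT_MAX_N or control.shape[0] > EXACT_MAX_N:
        res = stats.mannwhitneyu(
            case, control, alternative="two-sided", method="asymptotic", axis=0
        )
        p_raw = np.asarray(res.pvalue, dtype=float)
    else:
        p_raw = np.array(
            [wilcoxon_test(case[:, j], control[:, j])[1] for j in range(case.shape[1])]
        )

    cm = case.mean(axis=0)
    gm = control.mean(axis=0)
    fc = cm / gm
    out = pd.DataFrame(
        {
            "target_name": matrix.analytes.loc[analytes, "target_name"],
            "uniprot": matrix.analytes.loc[analytes, "uniprot"],
            "case_mean": cm,
            "control_mean": gm,
            "case_sem": case.std(axis=0, ddof=1) / np.sqrt(case.shape[0]),
            "control_sem": control.std(axis=0, ddof=1) / np.sqrt(control.shape[0]),
            "fc": fc,
            "log2fc": np.log2(fc),
            "p_raw": p_raw,
        },
        index=analytes,
    )
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["modulated"] = (out["p_adj"] < alpha) & (out["log2fc"].abs() > lfc)
    return out


def select_modulated(results: pd.DataFrame, alpha: float = ALPHA, lfc: float = LFC):
    """Analytes with ``p_adj < alpha`` and ``|log2fc| > lfc`` (both strict)."""
    if results.empty:
        return []
    keep = (results["p_adj"] < alpha) & (results["log2fc"].abs() > lfc)
    return list(results.index[keep])


# ---------------------------------------------------------------------------
# cohort summary (baseline-characteristics table)
# ---------------------------------------------------------------------------

def _continuous_row(case, control):
    case, control = np.asarray(case, float), np.asarray(control, float)
    msd = lambda x: f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"
    sp2 = (
        (case.size - 1) * np.var(case, ddof=1)
        + (control.size - 1) * np.var(control, ddof=1)
    ) / (case.size + control.size - 2)
    if sp2 == 0:
        # degenerate: both groups constant
        p = 1.0 if np.mean(case) == np.mean(control) else 0.0
        return msd(case), msd(control), "t-test (degenerate)", p
    p = stats.ttest_ind(case, control, equal_var=True).pvalue
    return msd(case), msd(control), "t-test", float(p)


def _categorical_row(case, control):
    levels = sorted(set(case) | set(control), key=str)
    table = np.array(
        [
            [sum(np.asarray(case, object) == lv) for lv in levels],
            [sum(np.asarray(control, object) == lv) for lv in levels],
        ]
    ).T  # levels × groups
    table = table[table.sum(axis=1) > 0]
    fmt = lambda col: "/".join(str(int(c)) for c in col)
    if table.shape[0] < 2:
        return fmt(table[:, 0]), fmt(table[:, 1]), "chi2 (degenerate)", 1.0
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected < 5).any():
        p = stats.fisher_exact(table).pvalue
        test = "fisher"
    else:
        p = stats.chi2_contingency(table, correction=(table.shape == (2, 2))).pvalue
        test = "chi2"
    return fmt(table[:, 0]), fmt(table[:, 1]), test, float(p)


def cohort_summary(samples: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Baseline-characteristics table comparing cases and controls.

    Continuous variables: mean ± SD per group and a two-sided pooled-variance
    t-test.  Categorical variables: per-level counts and a χ² test (Yates
    continuity correction for 2×2 tables) or Fisher's exact test when a 2×2
    expected count falls below 5.
    """
    if group_col not in samples.columns:
        raise ValueError(f"missing group column {group_col!r}")
    is_case = samples[group_col] == "case"
    rows = []
    for col in samples.columns:
        if col == group_col:
            continue
        series = samples[col]
        case, control = series[is_case], series[~is_case]
        numeric = pd.api.types.is_numeric_dtype(series) and series.nunique() > 4
        if numeric:
            c, g, test, p = _continuous_row(case, control)
        else:
            c, g, test, p = _categorical_row(case.tolist(), control.tolist())
        rows.append(
            {"variable": col, "case": c, "control": g, "test": test, "p": p}
        )
    return pd.DataFrame(rows).set_index("variable")
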