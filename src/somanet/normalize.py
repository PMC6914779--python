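"""Aptamer-array standardization: hybridization scaling, median normalization, QC.

Three steps, in assay order:

1. **Hybridization scale factors** — each sample carries spiked control
   sequences with predetermined reference RFUs.  Per sample, the factor is
   the median over controls of reference/measured; every value of the
   sample is multiplied by it.  This removes per-sample hybridization and
   readout bias.
2. **Median normalization** — per dilution set, the reference for each
   analyte is its median RFU across the sample group; the per-(sample,
   dilution set) factor is the median over that set's analytes of
   reference/measured, applied to all analytes of the set in that sample.
   This removes residual sample-level biases (total protein, pipetting).
3. **QC acceptance** — a sample is excluded when any of its median
   normalization factors falls outside the acceptance window, by default
   the closed interval [0.4, 2.5].

Medians of even-length vectors are the mean of the two middle values
throughout (numpy convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DILUTION_SETS, RFUMatrix

QC_WINDOW = (0.4, 2.5)


@dataclass
class ScaleFactorSet:
    """Per-sample normalization factors and QC status.

    Attributes
    ----------
    hyb_factor
        Series sample -> hybridization scale factor.
    median_factor
        DataFrame sample × dilution set of median-normalization factors.
    qc_status
        DataFrame sample × (status, reason); status in {"accepted",
        "excluded"}.
    """

    hyb_factor: pd.Series
    median_factor: pd.DataFrame
    qc_status: pd.DataFrame | None = None

    @property
    def accepted_samples(self) -> pd.Index:
        if self.qc_status is None:
            raise ValueError("qc_filter has not been applied")
        return self.qc_status.index[self.qc_status["status"] == "accepted"]

    def report(self) -> pd.DataFrame:
        """One row per sample: hyb factor, per-set factors, QC status."""
        out = pd.DataFrame({"hyb_factor": self.hyb_factor})
        for ds in self.median_factor.columns:
            out[f"median_factor_{ds}"] = self.median_factor[ds]
        if self.qc_status is not None:
            out["qc_status"] = self.qc_status["status"]
            out["qc_reason"] = self.qc_status["reason"]
        return out


def hybridization_scale_factors(raw: RFUMatrix):
    """Scale each sample by the median of reference/measured control ratios.

    Returns the scaled matrix and the per-sample factors.
    """
    controls = raw.hyb_controls
    if len(controls) == 0:
        raise ValueError("no hybridization controls present")
    refs = raw.analytes.loc[controls, "ref_rfu"].to_numpy(dtype=float)
    measured = raw.values[controls].to_numpy(dtype=float)
    if not np.all(measured > 0):
        raise ValueError("hybridization-control measurements must be > 0")
    ratios = refs[None, :] / measured
    factors = pd.Series(np.median(ratios, axis=1), index=raw.samples, name="hyb_factor")
    scaled = raw.values.mul(factors, axis=0)
    return RFUMatrix(scaled, raw.analytes.copy()), factors


def median_reference(matrix: RFUMatrix, group=None) -> pd.Series:
    """Per-analyte reference RFU: the median across the sample group."""
    if group is None:
        group = matrix.samples
    group = pd.Index(group)
    if len(group) < 2:
        raise ValueError("median normalization needs a group of >= 2 samples")
    hyb = matrix.analytes["is_hyb_control"].astype(bool)
    cols = matrix.analytes.index[~hyb]
    return matrix.values.loc[group, cols].median(axis=0)


def median_normalize(matrix: RFUMatrix, group=None, reference=None):
    """Per-dilution-set median normalization against a sample group.

    ``group`` is the set of samples whose per-analyte medians define the
    references (defaults to all samples of the matrix — e.g. one plate
    run); alternatively a precomputed per-analyte ``reference`` Series may
    be supplied, in which case normalization is an exact fixed point:
    re-applying with the same reference changes nothing.  Factors are
    computed and applied for every sample in the matrix.  Hybridization
    controls are left untouched: they are spiked oligos outside the plasma
    dilution sets.

    Returns the normalized matrix and a sample × dilution-set factor table.
    """
    if reference is None:
        reference = median_reference(matrix, group)

    values = matrix.values.copy()
    hyb = matrix.analytes["is_hyb_control"].astype(bool)
    dil = matrix.analytes.loc[~hyb, "dilution"]
    present = [ds for ds in DILUTION_SETS if (dil == ds).any()]
    if not present:
        raise ValueError("no plasma analytes in any dilution set")
    factors = pd.DataFrame(index=matrix.samples, columns=present, dtype=float)
    for ds in present:
        cols = dil.index[dil == ds]
        block = values[cols].to_numpy(dtype=float)
        ref = reference.loc[cols].to_numpy(dtype=float)
        ratio = ref[None, :] / block
        f = np.median(ratio, axis=1)
        factors[ds] = f
        values[cols] = block * f[:, None]
    return RFUMatrix(values, matrix.analytes.copy()), factors


def qc_filter(factors: ScaleFactorSet, window=QC_WINDOW) -> ScaleFactorSet:
    """Mark samples whose median factors fall outside the acceptance window.

    The window is a closed interval: boundary values are accepted.
    """
    low, high = float(window[0]), float(window[1])
    if low >= high:
        raise ValueError("QC window must satisfy low < high")
    status, reason = {}, {}
    for s in factors.median_factor.index:
        bad = []
        for ds in factors.median_factor.columns:
            f = factors.median_factor.loc[s, ds]
            if f < low:
                bad.append(f"{ds}: {f:.4g} < {low}")
            elif f > high:
                bad.append(f"{ds}: {f:.4g} > {high}")
        status[s] = "excluded" if bad else "accepted"
        reason[s] = "; ".join(bad)
    qc = pd.DataFrame({"status": pd.Series(status), "reason": pd.Series(reason)})
    qc = qc.loc[factors.median_factor.index]
    return ScaleFactorSet(factors.hyb_factor, factors.median_factor, qc)


def normalize_pipeline(raw: RFUMatrix, group=None, window=QC_WINDOW):
    """Hybridization scaling, median normalization, then QC exclusion.

    Returns
    -------
    (RFUMatrix, ScaleFactorSet)
        The normalized matrix restricted to QC-accepted samples, and the
        full factor set (all samples, with QC status).
    """
    scaled, hyb = hybridization_scale_factors(raw)
    normalized, med = median_normalize(scaled, group=group)
    sfs = qc_filter(ScaleFactorSet(hyb, med), window=window)
    kept = normalized.subset_samples(sfs.accepted_samples)
    return kept, sfs


def total_sample_scale(factors: ScaleFactorSet, analytes: pd.DataFrame) -> pd.Series:
    """Combined per-sample scale applied by normalization.

    Defined as hyb factor × the analyte-count-weighted geometric mean of
    the dilution-set median factors.  When normalization succeeds this is
    ~1/b for a sample with planted multiplicative bias b.
    """
    dil = analytes.loc[~analytes["is_hyb_control"].astype(bool), "dilution"]
    counts = dil.value_counts()
    weights = counts / counts.sum()
    log_m = np.log(factors.median_factor[list(weights.index)].to_numpy(dtype=float))
    combined = np.exp(log_m @ weights.to_numpy())
    return factors.hyb_factor * pd.Series(combined, index=factors.median_factor.index)
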