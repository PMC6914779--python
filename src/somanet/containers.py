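"""Shared in-memory containers for the aptamer-array pipeline.

The central object is :class:`RFUMatrix`: a samples × analytes table of
relative fluorescence units (RFU, the raw abundance scale of an aptamer
array) together with per-analyte metadata.  Analyte metadata carries the
fields the normalization stage needs: the dilution set each analyte was
measured in (aptamer panels split analytes over plasma dilutions, here
40% / 1% / 0.05%), a flag for spiked hybridization-control sequences, and
the predetermined reference RFU of each control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Dilution-set labels of the emulated assay.  Hybridization controls live in
#: their own pseudo-set "hyb": they are spiked oligos, not plasma analytes,
#: and are excluded from median normalization.
DILUTION_SETS = ("40%", "1%", "0.05%")
HYB_SET = "hyb"

#: Columns required in the analyte-metadata table.
ANALYTE_COLUMNS = ("target_name", "uniprot", "dilution", "is_hyb_control", "ref_rfu")


@dataclass
class RFUMatrix:
    """Samples × analytes RFU measurements plus analyte metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per analyte id;
        strictly positive, finite.
    analytes
        DataFrame indexed by analyte id with columns ``target_name``,
        ``uniprot``, ``dilution``, ``is_hyb_control`` and ``ref_rfu``
        (reference RFU, defined for hybridization controls only).
    """

    values: pd.DataFrame
    analytes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("RFU values must be finite")
        if not np.all(v > 0):
            raise ValueError("RFU values must be strictly positive")
        missing = [c for c in ANALYTE_COLUMNS if c not in self.analytes.columns]
        if missing:
            raise ValueError(f"analyte metadata missing columns: {missing}")
        if not self.values.columns.equals(self.analytes.index):
            if set(self.values.columns) != set(self.analytes.index):
                raise ValueError("values columns and analyte metadata disagree")
            # same analytes, different order: align metadata to the matrix
            self.analytes = self.analytes.loc[self.values.columns]
        bad = set(self.analytes["dilution"]) - set(DILUTION_SETS) - {HYB_SET}
        if bad:
            raise ValueError(f"unknown dilution sets: {sorted(bad)}")
        hyb = self.analytes["is_hyb_control"].astype(bool)
        if hyb.any():
            refs = self.analytes.loc[hyb, "ref_rfu"].to_numpy(dtype=float)
            if not (np.all(np.isfinite(refs)) and np.all(refs > 0)):
                raise ValueError("hybridization controls need a positive reference RFU")

    # -- convenience views -------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def hyb_controls(self) -> pd.Index:
        """Analyte ids of the hybridization controls."""
        return self.analytes.index[self.analytes["is_hyb_control"].astype(bool)]

    @property
    def assay_analytes(self) -> pd.Index:
        """Analyte ids of the plasma analytes (controls excluded)."""
        return self.analytes.index[~self.analytes["is_hyb_control"].astype(bool)]

    def copy(self) -> "RFUMatrix":
        return RFUMatrix(self.values.copy(), self.analytes.copy())

    def subset_samples(self, samples) -> "RFUMatrix":
        return RFUMatrix(self.values.loc[list(samples)], self.analytes.copy())


@dataclass
class SimGroundTruth:
    """Ground truth recorded by the generators for recovery tests."""

    signal_analytes: set = field(default_factory=set)
    true_effects: dict = field(default_factory=dict)  # analyte -> log2 shift
    sample_biases: dict = field(default_factory=dict)  # sample -> factor > 0
    planted_communities: dict = field(default_factory=dict)  # node -> community id
    planted_pathways: dict = field(default_factory=dict)  # name -> set of nodes
    analyte_map: dict = field(default_factory=dict)  # analyte -> list of node ids
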