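"""Reference values for the published six-protein cardiovascular-death signature.

The discovery study this pipeline re-implements reported, for each of the
six signature proteins, the case and control mean RFU (± SEM) on the
aptamer platform, the jackknife selection frequency, and the fold change
rounded to two decimals.  The printed group means are kept here as inputs
for worked examples and regression checks of the fold-change arithmetic:
``fc = case_mean / control_mean``.
"""

from __future__ import annotations

import pandas as pd

#: protein -> (UniProt, case mean RFU, control mean RFU, published FC,
#:             jackknife selection frequency)
SIGNATURE_REFERENCE = {
    "C3": ("P01024", 104221.0, 159620.0, 0.65, 1.00),
    "MAPK5": ("Q8IW41", 484.3, 413.6, 1.17, 0.97),
    "CATS": ("P25774", 752.6, 965.9, 0.78, 1.00),
    "MMP1": ("P03956", 1499.6, 766.4, 1.96, 1.00),
    "MMP7": ("P09237", 913.1, 635.1, 1.44, 1.00),
    "F107B": ("Q9H098", 812.4, 972.4, 0.84, 1.00),
}


def signature_reference_table() -> pd.DataFrame:
    """The published six-protein signature as a DataFrame."""
    return pd.DataFrame(
        [
            {
                "protein": name,
                "uniprot": u,
                "case_mean": cm,
                "control_mean": gm,
                "published_fc": fc,
                "frequency": fr,
            }
            for name, (u, cm, gm, fc, fr) in SIGNATURE_REFERENCE.items()
        ]
    ).set_index("protein")
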