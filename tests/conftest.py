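import numpy as np
import pandas as pd
import pytest

from somanet import GraphSimConfig, SimConfig, simulate_cohort, simulate_knowledge_graph
from somanet.containers import RFUMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted signals for fast stage tests."""
    config = SimConfig(
        n_case=20, n_control=20, n_analytes=80, n_signal=8,
        effect_log2fc=1.0, seed=3,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_graph():
    config = GraphSimConfig(
        n_communities=4, community_size=15, p_within=0.4, p_between=0.02, seed=5
    )
    return simulate_knowledge_graph(config, analyte_ids=[f"A{i + 1:05d}" for i in range(30)])


def make_rfu(values, dilutions=None, hyb=None, refs=None) -> RFUMatrix:
    """Hand-build a small RFUMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    analytes = [f"A{j + 1:03d}" for j in range(p)]
    hyb = [False] * p if hyb is None else list(hyb)
    if dilutions is None:
        dilutions = ["hyb" if h else "40%" for h in hyb]
    refs = [np.nan] * p if refs is None else list(refs)
    meta = pd.DataFrame(
        {
            "target_name": analytes,
            "uniprot": [""] * p,
            "dilution": dilutions,
            "is_hyb_control": hyb,
            "ref_rfu": refs,
        },
        index=pd.Index(analytes, name="analyte"),
    )
    frame = pd.DataFrame(
        values, index=pd.Index([f"S{i + 1:02d}" for i in range(n)], name="sample"),
        columns=analytes,
    )
    return RFUMatrix(frame, meta)
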