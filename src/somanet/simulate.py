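"""Synthetic cohorts, knowledge graphs and pathway sets with known ground truth.

The emulated study design: a matched case/control cohort of systolic
heart-failure patients (case = cardiovascular death within 3 years of
follow-up, control = alive), profiled on an aptamer array of ~1310 plasma
proteins with 12 spiked hybridization-control sequences per sample, and a
typed molecular-interaction knowledge graph (protein-coding genes, miRNAs,
metabolites) used downstream for seed-node network construction.

Generative model for the cohort
-------------------------------
RFU values are log-normal (strictly positive, right-skewed, like real
aptamer data).  For sample *s* and analyte *a*::

    log RFU[s, a] = mu_a + ln(2) * delta_a * 1[s is case] + ln(b_s) + eps,
    eps ~ N(0, rfu_scale**2)

where ``mu_a`` is the analyte baseline (spread ``analyte_spread`` across
analytes), ``delta_a`` is the planted log2 group shift (``effect_log2fc``
for the ``n_signal`` signal analytes, 0 otherwise), and ``b_s`` is a
per-sample multiplicative bias, ``log b_s ~ N(0, sample_bias_sd**2)``.
Hybridization controls carry the sample bias (times a small technical
noise ``hyb_noise_sd``) but never a group effect, so normalization can
recover ``1/b_s``.  The planted log2 fold change of a signal analyte is
exactly ``effect_log2fc`` in expectation.

The knowledge graph is a planted-partition graph: dense communities,
sparse between-community edges, plus one deterministic ring per community
so that each planted community is internally connected (``p_between = 0``
then yields exactly ``n_communities`` connected components).  One pathway
set per sufficiently large community is emitted for the enrichment stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import DILUTION_SETS, HYB_SET, RFUMatrix, SimGroundTruth

NODE_TYPES = ("protein-coding", "miRNA", "metabolite")


@dataclass
class SimConfig:
    """Cohort-generator settings; defaults are the emulated study conditions."""

    n_case: int = 84
    n_control: int = 84
    n_analytes: int = 1310
    n_signal: int = 25
    effect_log2fc: float = 1.0
    rfu_location: float = 7.0  # natural-log mean of baseline RFU (~1100 RFU)
    rfu_scale: float = 0.2  # within-analyte between-sample log-SD (~20% CV)
    analyte_spread: float = 1.5  # across-analyte SD of baselines
    n_hyb_controls: int = 12
    dilution_fractions: dict = field(
        default_factory=lambda: {"40%": 0.5, "1%": 0.3, "0.05%": 0.2}
    )
    sample_bias_sd: float = 0.3  # log-SD of per-sample multiplicative bias
    hyb_noise_sd: float = 0.05  # technical log-SD of control measurements
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case", "n_control", "n_analytes", "n_hyb_controls"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.n_signal <= self.n_analytes:
            raise ValueError("n_signal must lie in [0, n_analytes]")
        if not math.isfinite(self.effect_log2fc):
            raise ValueError("effect_log2fc must be finite")
        for name in ("rfu_scale", "analyte_spread", "sample_bias_sd", "hyb_noise_sd"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not math.isfinite(self.rfu_location):
            raise ValueError("rfu_location must be finite")
        if set(self.dilution_fractions) != set(DILUTION_SETS):
            raise ValueError(f"dilution_fractions must use labels {DILUTION_SETS}")
        if abs(sum(self.dilution_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("dilution_fractions must sum to 1")


@dataclass
class GraphSimConfig:
    """Planted-partition knowledge-graph settings."""

    n_communities: int = 8
    community_size: int = 25
    p_within: float = 0.3
    p_between: float = 0.005
    node_type_mix: tuple = (0.57, 0.37, 0.06)  # protein-coding, miRNA, metabolite
    seed: int = 0

    def validate(self) -> None:
        if self.n_communities <= 0 or self.community_size <= 0:
            raise ValueError("counts must be > 0")
        if not 0.0 <= self.p_between < self.p_within <= 1.0:
            raise ValueError("need 0 <= p_between < p_within <= 1")
        if len(self.node_type_mix) != 3 or abs(sum(self.node_type_mix) - 1.0) > 1e-9:
            raise ValueError("node_type_mix must be 3 proportions summing to 1")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _simulate_covariates(rng: np.random.Generator, group: np.ndarray) -> pd.DataFrame:
    """Clinical covariates with case/control shifts of the emulated cohort.

    Cases (CV death within 3 years) get higher NYHA class, higher BNP
    category, higher creatinine and markedly lower peak VO2; groups are
    matched on age, sex and aetiology.
    """
    n = group.size
    case = group == "case"
    cov = pd.DataFrame(index=pd.RangeIndex(n))
    cov["age"] = np.round(rng.normal(59.0, 10.0, n), 1)
    cov["sex_male"] = (rng.random(n) < 78 / 84).astype(int)
    cov["ischaemic"] = (rng.random(n) < 51 / 84).astype(int)
    cov["diabetes"] = (rng.random(n) < np.where(case, 53 / 84, 51 / 84)).astype(int)
    nyha_p = {
        True: np.array([0.02, 0.27, 0.55, 0.16]),
        False: np.array([0.18, 0.44, 0.31, 0.07]),
    }
    bnp_p = {
        True: np.array([14, 38, 29], dtype=float) / 81,
        False: np.array([36, 25, 20], dtype=float) / 81,
    }
    nyha = np.empty(n, dtype=int)
    bnp = np.empty(n, dtype=object)
    bnp_levels = np.array(["low", "intermediate", "high"], dtype=object)
    for i in range(n):
        nyha[i] = rng.choice(4, p=nyha_p[bool(case[i])]) + 1
        bnp[i] = bnp_levels[rng.choice(3, p=bnp_p[bool(case[i])])]
    cov["nyha"] = nyha
    cov["bnp_category"] = bnp
    cov["lvef"] = np.clip(
        np.where(case, rng.normal(28.1, 9.9, n), rng.normal(29.3, 9.2, n)), 10, 45
    ).round(1)
    cov["peak_vo2"] = np.clip(
        np.where(case, rng.normal(10.5, 1.7, n), rng.normal(21.0, 5.2, n)), 4, None
    ).round(1)
    cov["creatinine"] = np.clip(
        np.where(case, rng.normal(12.55, 3.55, n), rng.normal(11.12, 2.63, n)), 3, None
    ).round(2)
    cov["ace_inhibitor"] = (rng.random(n) < np.where(case, 77 / 84, 76 / 84)).astype(int)
    cov["beta_blocker"] = (rng.random(n) < np.where(case, 76 / 84, 78 / 84)).astype(int)
    cov["diuretic"] = (rng.random(n) < np.where(case, 75 / 84, 65 / 84)).astype(int)
    return cov


def simulate_cohort(config: SimConfig):
    """Generate a synthetic aptamer-array cohort.

    Returns
    -------
    (RFUMatrix, pandas.DataFrame, SimGroundTruth)
        The raw (biased, un-normalized) RFU matrix, the sample table with a
        ``group`` column plus clinical covariates, and the ground truth
        (signal analytes, planted log2 effects, per-sample biases).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control

    sample_ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample")
    group = np.array(["case"] * config.n_case + ["control"] * config.n_control)

    analyte_ids = [f"A{i + 1:05d}" for i in range(config.n_analytes)]
    hyb_ids = [f"HCE{i + 1:02d}" for i in range(config.n_hyb_controls)]

    # dilution-set assignment by configured proportions (deterministic split)
    counts = {
        lab: int(round(frac * config.n_analytes))
        for lab, frac in config.dilution_fractions.items()
    }
    # fix rounding drift on the largest set
    drift = config.n_analytes - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    dilutions = []
    for lab in DILUTION_SETS:
        dilutions.extend([lab] * counts[lab])
    dilutions = np.array(dilutions[: config.n_analytes])

    baselines = config.rfu_location + config.analyte_spread * rng.standard_normal(
        config.n_analytes
    )
    signal = list(rng.choice(config.n_analytes, size=config.n_signal, replace=False))
    effects = np.zeros(config.n_analytes)
    effects[signal] = config.effect_log2fc

    log_bias = config.sample_bias_sd * rng.standard_normal(n)

    eps = config.rfu_scale * rng.standard_normal((n, config.n_analytes))
    log_values = (
        baselines[None, :]
        + math.log(2.0) * effects[None, :] * (group == "case")[:, None]
        + log_bias[:, None]
        + eps
    )

    hyb_refs = np.exp(
        config.rfu_location + 0.5 * rng.standard_normal(config.n_hyb_controls)
    )
    hyb_eps = config.hyb_noise_sd * rng.standard_normal((n, config.n_hyb_controls))
    hyb_values = hyb_refs[None, :] * np.exp(log_bias[:, None] + hyb_eps)

    values = pd.DataFrame(
        np.hstack([np.exp(log_values), hyb_values]),
        index=sample_ids,
        columns=analyte_ids + hyb_ids,
    )
    analytes = pd.DataFrame(
        {
            "target_name": [f"Target_{a}" for a in analyte_ids]
            + [f"HybControl_{i + 1}" for i in range(config.n_hyb_controls)],
            "uniprot": [f"P{i + 1:05d}" for i in range(config.n_analytes)]
            + [""] * config.n_hyb_controls,
            "dilution": list(dilutions) + [HYB_SET] * config.n_hyb_controls,
            "is_hyb_control": [False] * config.n_analytes
            + [True] * config.n_hyb_controls,
            "ref_rfu": [np.nan] * config.n_analytes + list(hyb_refs),
        },
        index=pd.Index(analyte_ids + hyb_ids, name="analyte"),
    )

    sample_table = pd.DataFrame({"group": group}, index=sample_ids)
    cov = _simulate_covariates(rng, group)
    cov.index = sample_ids
    sample_table = pd.concat([sample_table, cov], axis=1)

    truth = SimGroundTruth(
        signal_analytes={analyte_ids[i] for i in signal},
        true_effects={analyte_ids[i]: float(effects[i]) for i in signal},
        sample_biases=dict(zip(sample_ids, np.exp(log_bias))),
    )
    return RFUMatrix(values, analytes), sample_table, truth


# ---------------------------------------------------------------------------
# knowledge graph
# ---------------------------------------------------------------------------

def simulate_knowledge_graph(config: GraphSimConfig, analyte_ids=None):
    """Generate a planted-partition knowledge graph plus pathway sets.

    Parameters
    ----------
    config
        Planted-partition settings.
    analyte_ids
        Optional sequence of analyte ids; when given, a one-to-many mapping
        from analytes to graph nodes is emitted in the ground truth (about
        5% of analytes map to two nodes, mirroring assays where one protein
        is targeted by multiple reagents or maps to multiple gene nodes).

    Returns
    -------
    (networkx.Graph, dict, SimGroundTruth)
        The undirected simple graph (node attributes ``node_type``,
        ``display_name``; edge attribute ``sources``), the pathway sets as
        ``{name: set of node ids}``, and the ground truth with the planted
        community partition and the analyte -> nodes mapping.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_nodes = config.n_communities * config.community_size
    node_ids = [f"N{i + 1:05d}" for i in range(n_nodes)]
    community = {
        node_ids[i]: i // config.community_size for i in range(n_nodes)
    }
    types = rng.choice(NODE_TYPES, size=n_nodes, p=list(config.node_type_mix))

    g = nx.Graph()
    for i, nid in enumerate(node_ids):
        g.add_node(nid, node_type=str(types[i]), display_name=f"Mol_{nid}")

    cs = config.community_size
    for c in range(config.n_communities):
        members = node_ids[c * cs : (c + 1) * cs]
        # deterministic ring keeps each planted community internally connected
        if cs > 1:
            for i in range(cs):
                g.add_edge(members[i], members[(i + 1) % cs], sources="sim")
        draws = rng.random((cs, cs))
        for i in range(cs):
            for j in range(i + 1, cs):
                if draws[i, j] < config.p_within:
                    g.add_edge(members[i], members[j], sources="sim")
    if config.p_between > 0:
        for c1 in range(config.n_communities):
            for c2 in range(c1 + 1, config.n_communities):
                a = node_ids[c1 * cs : (c1 + 1) * cs]
                b = node_ids[c2 * cs : (c2 + 1) * cs]
                draws = rng.random((cs, cs))
                for i in range(cs):
                    for j in range(cs):
                        if draws[i, j] < config.p_between:
                            g.add_edge(a[i], b[j], sources="sim")

    pathways = {}
    for c in range(config.n_communities):
        members = set(node_ids[c * cs : (c + 1) * cs])
        if 10 <= len(members) <= 500:
            pathways[f"PW{c + 1:03d}"] = members

    analyte_map = {}
    if analyte_ids is not None:
        analyte_ids = list(analyte_ids)
        targets = rng.choice(n_nodes, size=len(analyte_ids), replace=len(analyte_ids) > n_nodes)
        double = rng.random(len(analyte_ids)) < 0.05
        for k, a in enumerate(analyte_ids):
            nodes = [node_ids[targets[k]]]
            if double[k]:
                extra = node_ids[int(rng.integers(n_nodes))]
                if extra not in nodes:
                    nodes.append(extra)
            analyte_map[a] = nodes

    truth = SimGroundTruth(
        planted_communities=community,
        planted_pathways=pathways,
        analyte_map=analyte_map,
    )
    return g, pathways, truth
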