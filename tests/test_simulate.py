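import networkx as nx
import numpy as np
import pytest
from scipy import stats

from somanet import GraphSimConfig, SimConfig, simulate_cohort, simulate_knowledge_graph


class TestCohortGenerator:
    def test_seed_reproducibility(self):
        config = SimConfig(n_case=6, n_control=6, n_analytes=30, n_signal=3, seed=7)
        a = simulate_cohort(config)
        b = simulate_cohort(config)
        assert a[0].values.equals(b[0].values)
        assert a[1].equals(b[1])
        assert a[2].signal_analytes == b[2].signal_analytes

    def test_values_positive_and_shaped(self, small_cohort):
        matrix, samples, truth = small_cohort
        assert (matrix.values.to_numpy() > 0).all()
        assert matrix.values.shape == (40, 80 + 12)
        assert len(matrix.hyb_controls) == 12
        assert set(truth.signal_analytes) <= set(matrix.assay_analytes)
        assert all(b > 0 for b in truth.sample_biases.values())
        assert (samples["group"].value_counts() == [20, 20]).all()

    def test_signal_analytes_hit_planted_fold_change(self):
        """Signal analytes with a +1 log2 shift show a case/control mean
        ratio near 2 (within [1.7, 2.3] for at least 4 of the 5 signals)."""
        config = SimConfig(
            n_case=84, n_control=84, n_analytes=50, n_signal=5,
            effect_log2fc=1.0, seed=21,
        )
        matrix, samples, truth = simulate_cohort(config)
        case = samples.index[samples["group"] == "case"]
        control = samples.index[samples["group"] == "control"]
        hits = 0
        for analyte in truth.signal_analytes:
            ratio = (
                matrix.values.loc[case, analyte].mean()
                / matrix.values.loc[control, analyte].mean()
            )
            hits += 1.7 <= ratio <= 2.3
        assert hits >= 4

    def test_null_simulation_calibrated(self):
        """With no planted effect the raw Wilcoxon p-values are uniform:
        about 5% of analytes fall below 0.05."""
        fracs = []
        for seed in range(4):
            config = SimConfig(
                n_case=30, n_control=30, n_analytes=250, n_signal=0,
                effect_log2fc=0.0, sample_bias_sd=0.0, seed=seed,
            )
            matrix, samples, _ = simulate_cohort(config)
            case = matrix.values.loc[samples["group"] == "case", matrix.assay_analytes]
            control = matrix.values.loc[samples["group"] == "control", matrix.assay_analytes]
            p = stats.mannwhitneyu(case, control, axis=0).pvalue
            fracs.append(np.mean(p < 0.05))
        assert abs(np.mean(fracs) - 0.05) < 0.02

    def test_hyb_controls_carry_bias_not_group_effect(self):
        config = SimConfig(
            n_case=40, n_control=40, n_analytes=20, n_signal=5,
            effect_log2fc=2.0, sample_bias_sd=0.4, hyb_noise_sd=0.01, seed=9,
        )
        matrix, samples, truth = simulate_cohort(config)
        controls = matrix.hyb_controls
        refs = matrix.analytes.loc[controls, "ref_rfu"].to_numpy()
        biases = np.array([truth.sample_biases[s] for s in matrix.samples])
        # measured / reference tracks the sample bias
        ratio = matrix.values[controls].to_numpy() / refs[None, :]
        assert np.allclose(np.median(ratio, axis=1), biases, rtol=0.05)
        # and is independent of group
        case = samples["group"].to_numpy() == "case"
        logr = np.log(ratio / biases[:, None]).mean(axis=1)
        assert abs(logr[case].mean() - logr[~case].mean()) < 0.02

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_case": 0},
            {"n_signal": 1000},
            {"effect_log2fc": float("nan")},
            {"rfu_scale": -1.0},
            {"rfu_location": float("inf")},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_cohort(SimConfig(**{"n_analytes": 10, "n_signal": 2, **bad}))


class TestGraphGenerator:
    def test_seed_reproducibility(self):
        config = GraphSimConfig(n_communities=3, community_size=12, seed=4)
        g1, p1, t1 = simulate_knowledge_graph(config, analyte_ids=["A1", "A2"])
        g2, p2, t2 = simulate_knowledge_graph(config, analyte_ids=["A1", "A2"])
        assert sorted(g1.edges) == sorted(g2.edges)
        assert t1.analyte_map == t2.analyte_map

    def test_zero_between_gives_disconnected_communities(self):
        config = GraphSimConfig(
            n_communities=5, community_size=12, p_within=0.3, p_between=0.0, seed=1
        )
        g, _, truth = simulate_knowledge_graph(config)
        assert nx.number_connected_components(g) == 5
        comps = [set(c) for c in nx.connected_components(g)]
        planted = {}
        for node, cid in truth.planted_communities.items():
            planted.setdefault(cid, set()).add(node)
        assert sorted(map(frozenset, comps)) == sorted(map(frozenset, planted.values()))

    def test_simple_graph_and_types(self, small_graph):
        g, pathways, truth = small_graph
        assert nx.number_of_selfloops(g) == 0
        types = set(nx.get_node_attributes(g, "node_type").values())
        assert types <= {"protein-coding", "miRNA", "metabolite"}
        for members in pathways.values():
            assert 10 <= len(members) <= 500
            assert members <= set(g.nodes)
        # mapping covers the analytes and points into the graph
        assert set(truth.analyte_map) == {f"A{i + 1:05d}" for i in range(30)}
        for nodes in truth.analyte_map.values():
            assert nodes and all(n in g for n in nodes)

    def test_within_denser_than_between(self, small_graph):
        g, _, truth = small_graph
        comm = truth.planted_communities
        within = between = 0
        for u, v in g.edges:
            if comm[u] == comm[v]:
                within += 1
            else:
                between += 1
        n, k = 15, 4
        possible_within = k * n * (n - 1) / 2
        possible_between = (k * n) ** 2 / 2 - k * n * n / 2
        assert within / possible_within > between / possible_between

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            simulate_knowledge_graph(GraphSimConfig(p_within=0.1, p_between=0.2))
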