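import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somanet import (
    bh_adjust,
    cohort_summary,
    differential_table,
    fold_change,
    normalize_pipeline,
    select_modulated,
    wilcoxon_test,
)
from _oracles import bh_adjust_brute, wilcoxon_exact_two_sided


def vector_with(mean, sd, n, seed=0):
    """A vector with exactly the requested mean and (ddof=1) SD."""
    z = np.random.default_rng(seed).standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestWilcoxon:
    @pytest.mark.parametrize(
        "case, control, expected",
        [
            ((1, 2, 3), (4, 5, 6), 0.1),
            ((1, 2), (3, 4), 1 / 3),
        ],
    )
    def test_exact_small_sample_values(self, case, control, expected):
        _, p = wilcoxon_test(case, control)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_test((1, 2, 3), (1, 2, 3))
        assert p == pytest.approx(1.0)

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n1, n2 = rng.integers(2, 9, size=2)
            values = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            case, control = values[:n1], values[n1:]
            _, p = wilcoxon_test(case, control)
            assert p == pytest.approx(wilcoxon_exact_two_sided(case, control), abs=1e-12)

    def test_rank_sum_statistic(self):
        w, _ = wilcoxon_test((4, 5, 6), (1, 2, 3))
        assert w == 15.0  # ranks 4+5+6

    def test_empty_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_test((), (1, 2))
        with pytest.raises(ValueError):
            wilcoxon_test((1, np.nan), (1, 2))


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)),
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.005, 0.9), (0.01, 0.9)),
        ],
    )
    def test_hand_computed_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_matches_step_up_formula_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        assert adj == pytest.approx(bh_adjust_brute(p))
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_order_invariance(self):
        p = [0.04, 0.001, 0.3, 0.02, 0.9]
        adj = bh_adjust(p)
        perm = [2, 0, 4, 1, 3]
        adj_perm = bh_adjust([p[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFoldChange:
    @pytest.mark.parametrize(
        "case_mean, control_mean, expected",
        [
            (1499.6, 766.4, 1.96),  # strong up-regulation
            (104221.0, 159620.0, 0.65),  # strong down-regulation
        ],
    )
    def test_reported_style_ratios(self, case_mean, control_mean, expected):
        out = fold_change(vector_with(case_mean, 1.0, 10), vector_with(control_mean, 1.0, 10))
        assert round(out["fc"], 2) == expected

    def test_equal_means(self):
        out = fold_change([2.0, 4.0], [1.0, 5.0])
        assert out["fc"] == pytest.approx(1.0)
        assert out["log2fc"] == pytest.approx(0.0)

    def test_scale_equivariance(self):
        case, control = [1.0, 2.0, 3.0], [2.0, 2.5, 3.5]
        a = fold_change(case, control)
        b = fold_change([7.3 * v for v in case], [7.3 * v for v in control])
        assert a["fc"] == pytest.approx(b["fc"])

    def test_sem(self):
        out = fold_change([1.0, 2.0, 3.0], [4.0, 4.0])
        assert out["case_sem"] == pytest.approx(1.0 / np.sqrt(3))
        assert out["control_sem"] == 0.0


class TestSelectModulated:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["p_adj", "log2fc"],
                            index=[f"A{i}" for i in range(len(rows))])

    def test_threshold_logic(self):
        df = self._frame([(0.01, 0.30), (0.01, 0.20), (0.06, 0.50), (0.04, -0.26)])
        assert select_modulated(df) == ["A0", "A3"]

    def test_boundaries_are_strict(self):
        df = self._frame([(0.05, 0.50), (0.01, 0.25)])
        assert select_modulated(df) == []

    def test_empty_table(self):
        assert select_modulated(pd.DataFrame()) == []


class TestDifferentialTable:
    def test_planted_signals_recovered(self, small_cohort):
        matrix, samples, truth = small_cohort
        normalized, _ = normalize_pipeline(matrix)
        table = differential_table(normalized, samples.loc[normalized.samples])
        assert set(table.index) == set(matrix.assay_analytes)
        assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()
        assert np.allclose(table["log2fc"], np.log2(table["fc"]))
        modulated = set(select_modulated(table))
        # strong planted effects should dominate the modulated set
        assert truth.signal_analytes <= modulated
        assert len(modulated - truth.signal_analytes) <= 3


class TestCohortSummary:
    def test_continuous_variable_pooled_t(self):
        case = vector_with(12.55, 3.55, 84, seed=1)
        control = vector_with(11.12, 2.63, 84, seed=2)
        samples = pd.DataFrame(
            {
                "group": ["case"] * 84 + ["control"] * 84,
                "creatinine": np.concatenate([case, control]),
            }
        )
        row = cohort_summary(samples).loc["creatinine"]
        assert row["test"] == "t-test"
        assert row["p"] == pytest.approx(0.003, abs=5e-4)

    def test_2x2_categorical_yates_chi2(self):
        diabetes = [1] * 53 + [0] * 31 + [1] * 51 + [0] * 33
        samples = pd.DataFrame(
            {"group": ["case"] * 84 + ["control"] * 84, "diabetes": diabetes}
        )
        row = cohort_summary(samples).loc["diabetes"]
        assert row["test"] == "chi2"
        assert row["p"] == pytest.approx(0.874, abs=5e-4)

    def test_sparse_table_uses_fisher(self):
        samples = pd.DataFrame(
            {"group": ["case"] * 10 + ["control"] * 10,
             "rare": [1] * 2 + [0] * 8 + [1] * 1 + [0] * 9}
        )
        assert cohort_summary(samples).loc["rare", "test"] == "fisher"

    def test_degenerate_variable_reported_not_crashed(self):
        samples = pd.DataFrame(
            {"group": ["case"] * 5 + ["control"] * 5, "constant": [7.7] * 10}
        )
        row = cohort_summary(samples).loc["constant"]
        assert row["p"] == 1.0
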