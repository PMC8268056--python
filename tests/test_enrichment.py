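"""Panel statistics, overexpression calls, consensus rules, fold changes.

Each operation is checked against an independent brute-force
reimplementation on randomized inputs, plus the closed-form examples.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protfunnel.enrichment import (
    CallSet,
    EnrichmentError,
    aggregate_fold_change,
    call_above_average_all_samples,
    call_above_average_dataset_mean,
    consensus_intersection,
    consensus_k_of_n,
    fold_change_tumor_vs_normal,
    high_expression_cutoff,
    panel_stats,
    relative_to_reference_tissue,
    venn_regions,
)

from conftest import make_catalog, make_dataset


def random_panel_dataset(rng, n_genes=30, n_samples=8, groups=None):
    genes = [f"G{i}" for i in range(n_genes)]
    values = rng.uniform(0.1, 100.0, size=(n_genes, n_samples))
    groups = groups or ["tumor"] * n_samples
    catalog = make_catalog(**{g: {"extracellular"} for g in genes})
    return make_dataset(values, genes, groups), catalog


class TestPanelStats:
    def test_closed_form_mean_and_sd(self):
        ds = make_dataset([[1.0], [2.0], [3.0]], ["A", "B", "C"], ["tumor"])
        cat = make_catalog(A={"extracellular"}, B={"extracellular"}, C={"extracellular"})
        stats = panel_stats(ds, cat)
        assert stats.panel_mean == 2.0
        assert stats.panel_sd == 1.0
        assert stats.n_values == 3

    def test_constant_matrix_has_zero_sd(self):
        ds = make_dataset([[5.0, 5.0], [5.0, 5.0]], ["A", "B"], ["tumor", "tumor"])
        cat = make_catalog(A={"extracellular"}, B={"extracellular"})
        stats = panel_stats(ds, cat)
        assert (stats.panel_mean, stats.panel_sd) == (5.0, 0.0)

    def test_matches_two_pass_brute_force(self):
        rng = np.random.default_rng(1)
        ds, cat = random_panel_dataset(rng, 30, 10)
        stats = panel_stats(ds, cat)
        flat = [ds.matrix.loc[g, s] for g in ds.gene_index for s in ds.sample_ids]
        mean = sum(flat) / len(flat)
        sd = math.sqrt(sum((v - mean) ** 2 for v in flat) / (len(flat) - 1))
        assert stats.panel_mean == pytest.approx(mean, rel=1e-12)
        assert stats.panel_sd == pytest.approx(sd, rel=1e-12)

    def test_non_panel_genes_excluded(self):
        ds = make_dataset([[1.0], [2.0], [100.0]], ["A", "B", "ACTB"], ["tumor"])
        cat = make_catalog(A={"extracellular"}, B={"extracellular"})
        assert panel_stats(ds, cat).panel_mean == 1.5

    def test_fewer_than_two_panel_genes_is_error(self):
        ds = make_dataset([[1.0], [2.0]], ["A", "X"], ["tumor"])
        cat = make_catalog(A={"extracellular"})
        with pytest.raises(EnrichmentError, match="panel genes"):
            panel_stats(ds, cat)


class TestHighExpressionCutoff:
    @pytest.mark.parametrize(
        "mean,sd,k,expected",
        [(2.0, 1.0, 1.5, 3.5), (7.0, 0.0, 1.5, 7.0), (2.0, 1.0, 0.0, 2.0)],
    )
    def test_mean_plus_k_sd(self, mean, sd, k, expected):
        from protfunnel.enrichment import PanelStats

        stats = PanelStats("D", mean, sd, 10)
        assert high_expression_cutoff(stats, k) == expected

    def test_negative_multiplier_rejected(self):
        from protfunnel.enrichment import PanelStats

        with pytest.raises(EnrichmentError):
            high_expression_cutoff(PanelStats("D", 1.0, 1.0, 4), k=-1)


class TestAboveAverageCalls:
    def test_every_sample_rule(self):
        # panel mean = 4; gene A above it in both samples, B fails one
        ds = make_dataset(
            [[5.0, 7.0], [5.0, 3.0], [2.0, 2.0]],
            ["A", "B", "C"],
            ["cell_line", "cell_line"],
        )
        cat = make_catalog(A={"extracellular"}, B={"extracellular"}, C={"extracellular"})
        assert call_above_average_all_samples(ds, cat).genes == {"A"}

    def test_dataset_mean_rule_is_strict(self):
        # gene exactly at the panel mean is never called
        ds = make_dataset([[6.0], [4.0], [2.0]], ["A", "B", "C"], ["tumor"])
        cat = make_catalog(A={"extracellular"}, B={"extracellular"}, C={"extracellular"})
        assert call_above_average_dataset_mean(ds, cat).genes == {"A"}

    def test_dataset_mean_uses_selected_groups_only(self):
        ds = make_dataset(
            [[10.0, 1.0], [2.0, 1.0]],
            ["A", "B"],
            ["tumor", "adjacent_normal"],
        )
        cat = make_catalog(A={"extracellular"}, B={"extracellular"})
        cs = call_above_average_dataset_mean(ds, cat, groups_used=("tumor",))
        assert cs.genes == {"A"}  # panel mean over tumor column only = 6
        with pytest.raises(EnrichmentError):
            call_above_average_dataset_mean(ds, cat, groups_used=("leukocyte",))

    def test_both_rules_match_brute_force(self):
        rng = np.random.default_rng(2)
        ds, cat = random_panel_dataset(rng, 40, 6)
        values = ds.matrix.to_numpy()
        mean = values.mean()
        expected_all = {
            g for i, g in enumerate(ds.gene_index) if all(v > mean for v in values[i])
        }
        expected_mean = {
            g for i, g in enumerate(ds.gene_index) if values[i].mean() > mean
        }
        assert call_above_average_all_samples(ds, cat).genes == expected_all
        assert call_above_average_dataset_mean(ds, cat).genes == expected_mean


class TestConsensus:
    def cs(self, *gene_sets):
        return [
            CallSet(f"D{i}", "above_average_all_samples", frozenset(g))
            for i, g in enumerate(gene_sets)
        ]

    def test_intersection_and_identity(self):
        shared, regions = consensus_intersection(
            self.cs({"ADAM9", "ADAM10", "CTSB"}, {"ADAM9", "CTSB"}, {"ADAM9"})
        )
        assert shared == {"ADAM9"}
        assert regions["111"] == 1
        same, _ = consensus_intersection(self.cs({"A", "B"}, {"A", "B"}))
        assert same == {"A", "B"}

    def test_venn_regions_sum_to_union(self):
        rng = np.random.default_rng(3)
        sets = [
            set(rng.choice(20, size=rng.integers(5, 15), replace=False).tolist())
            for _ in range(3)
        ]
        regions = venn_regions(self.cs(*sets))
        assert sum(regions.values()) == len(set().union(*sets))

    def test_five_of_six_membership(self):
        sets = [{"ADAM9", "X"}] * 5 + [{"X"}]
        assert consensus_k_of_n(self.cs(*sets), k=5) == {"ADAM9", "X"}
        assert consensus_k_of_n(self.cs(*sets), k=6) == {"X"}

    def test_k_out_of_range_rejected(self):
        with pytest.raises(EnrichmentError):
            consensus_k_of_n(self.cs({"A"}, {"A"}), k=0)
        with pytest.raises(EnrichmentError):
            consensus_k_of_n(self.cs({"A"}, {"A"}), k=3)


gene_sets_st = st.lists(
    st.sets(st.integers(0, 15).map(lambda i: f"G{i}"), max_size=12),
    min_size=2,
    max_size=6,
)


@settings(max_examples=200, derandomize=True)
@given(sets=gene_sets_st, data=st.data())
def test_k_of_n_brute_force_boundaries_and_monotonicity(sets, data):
    """k-of-n equals brute-force counting; k=n is intersection, k=1 union;
    survivors shrink as k grows."""
    callsets = [CallSet(f"D{i}", "r", frozenset(s)) for i, s in enumerate(sets)]
    n = len(callsets)
    k = data.draw(st.integers(1, n))
    result = consensus_k_of_n(callsets, k)
    union = set().union(*sets)
    assert result == {g for g in union if sum(g in s for s in sets) >= k}
    assert consensus_k_of_n(callsets, 1) == union
    inter = set(sets[0]).intersection(*sets[1:])
    assert consensus_k_of_n(callsets, n) == inter
    if k < n:
        assert consensus_k_of_n(callsets, k + 1) <= result


class TestFoldChange:
    def test_ratio_of_group_means(self, paired_dataset):
        # ADAM9: tumor mean 6, normal mean 4
        assert fold_change_tumor_vs_normal(paired_dataset, "ADAM9") == 1.5
        assert fold_change_tumor_vs_normal(paired_dataset, "CTSB") == 1.0

    def test_missing_gene_or_groups_rejected(self, paired_dataset):
        with pytest.raises(EnrichmentError, match="MMP2"):
            fold_change_tumor_vs_normal(paired_dataset, "MMP2")
        tumor_only = make_dataset([[1.0, 2.0]], ["A"], ["tumor", "tumor"])
        with pytest.raises(EnrichmentError, match="adjacent_normal"):
            fold_change_tumor_vs_normal(tumor_only, "A")

    def test_random_data_matches_two_mean_ratio(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(1, 50, size=(5, 8))
        groups = ["tumor"] * 4 + ["adjacent_normal"] * 4
        ds = make_dataset(values, [f"G{i}" for i in range(5)], groups)
        for i in range(5):
            expected = values[i, :4].mean() / values[i, 4:].mean()
            assert fold_change_tumor_vs_normal(ds, f"G{i}") == pytest.approx(expected)

    @pytest.mark.parametrize(
        "fcs,method,expected",
        [
            ([1.2, 1.8], "arithmetic", 1.5),
            ([2.0], "arithmetic", 2.0),
            ([2.0, 8.0], "geometric", 4.0),
        ],
    )
    def test_aggregation(self, fcs, method, expected):
        assert aggregate_fold_change(fcs, method) == pytest.approx(expected)

    def test_aggregation_rejects_empty_and_nonpositive(self):
        with pytest.raises(EnrichmentError):
            aggregate_fold_change([])
        with pytest.raises(EnrichmentError):
            aggregate_fold_change([1.0, 0.0])


class TestRelativeToReference:
    def test_plain_ratio_of_means(self):
        target = make_dataset([[2.0, 2.0]], ["A"], ["leukocyte", "leukocyte"], "T")
        ref = make_dataset([[4.0, 4.0]], ["A"], ["tumor", "tumor"], "R")
        assert relative_to_reference_tissue(target, ref, "A") == 0.5

    def test_normalizer_cancels_platform_scale(self):
        rng = np.random.default_rng(5)
        vals_t = rng.uniform(1, 10, size=(2, 3))
        vals_r = rng.uniform(1, 10, size=(2, 3))
        target = make_dataset(vals_t, ["A", "ACTB"], ["organ"] * 3, "T")
        ref = make_dataset(vals_r, ["A", "ACTB"], ["tumor"] * 3, "R")
        base = relative_to_reference_tissue(target, ref, "A", "ACTB")
        scaled_t = make_dataset(vals_t * 10, ["A", "ACTB"], ["organ"] * 3, "T")
        scaled_r = make_dataset(vals_r * 0.3, ["A", "ACTB"], ["tumor"] * 3, "R")
        assert relative_to_reference_tissue(
            scaled_t, scaled_r, "A", "ACTB"
        ) == pytest.approx(base, rel=1e-12)
        expected = (vals_t[0].mean() / vals_t[1].mean()) / (
            vals_r[0].mean() / vals_r[1].mean()
        )
        assert base == pytest.approx(expected, rel=1e-12)

    def test_same_dataset_with_group_selectors(self):
        ds = make_dataset(
            [[1.0, 1.0, 10.0, 10.0]],
            ["A"],
            ["leukocyte", "leukocyte", "tumor", "tumor"],
        )
        ratio = relative_to_reference_tissue(
            ds, ds, "A", target_groups=("leukocyte",), reference_groups=("tumor",)
        )
        assert ratio == pytest.approx(0.1)

    def test_zero_reference_rejected(self):
        target = make_dataset([[1.0]], ["A"], ["organ"], "T")
        ref = make_dataset([[0.0]], ["A"], ["tumor"], "R")
        with pytest.raises(EnrichmentError):
            relative_to_reference_tissue(target, ref, "A")


@settings(max_examples=60, derandomize=True)
@given(
    c=st.floats(0.01, 1e3),
    seed=st.integers(0, 100),
)
def test_scale_invariance_of_calls_and_cutoff(c, seed):
    """Rescaling a dataset by c leaves call membership unchanged and scales
    panel statistics and the high-expression cutoff by exactly c."""
    rng = np.random.default_rng(seed)
    ds, cat = random_panel_dataset(rng, 15, 4)
    scaled = make_dataset(
        ds.matrix.to_numpy() * c, ds.gene_index, ["tumor"] * 4
    )
    assert (
        call_above_average_all_samples(ds, cat).genes
        == call_above_average_all_samples(scaled, cat).genes
    )
    assert (
        call_above_average_dataset_mean(ds, cat).genes
        == call_above_average_dataset_mean(scaled, cat).genes
    )
    s1, s2 = panel_stats(ds, cat), panel_stats(scaled, cat)
    assert s2.panel_mean == pytest.approx(c * s1.panel_mean, rel=1e-9)
    assert s2.panel_sd == pytest.approx(c * s1.panel_sd, rel=1e-9)
    assert high_expression_cutoff(s2) == pytest.approx(
        c * high_expression_cutoff(s1), rel=1e-9
    )
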