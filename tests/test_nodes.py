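"""Node profiles, condition-specific calls, high-expression rule,
annotation overlay and Tatami rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import somcoex as sx


def _toy_profile():
    """2x2 grid, one substrate, two growth points, hand-set means."""
    cols = pd.MultiIndex.from_tuples(
        [("AH", 1), ("AH", 2)], names=["substrate", "growth_point"]
    )
    means = pd.DataFrame(
        [[4.0, 6.5], [10.5, 10.5], [10.2, 10.2], [np.nan, np.nan]],
        index=pd.Index([1, 2, 3, 4], name="node_id"),
        columns=cols,
    )
    folds = pd.DataFrame(
        {("AH", 2): means[("AH", 2)] - means[("AH", 1)]},
    )
    folds.columns = pd.MultiIndex.from_tuples([("AH", 2)], names=["substrate", "growth_point"])
    counts = pd.Series([1, 2, 2, 0], index=means.index, name="member_count")
    return sx.NodeProfile(means, folds, counts)


class TestNodeConditionMeans:
    def test_single_gene_node_mean(self, toy_metadata):
        vals = pd.DataFrame(
            [[4.0, 4.0, 6.5, 6.5]], index=["g1"], columns=["s1", "s2", "s3", "s4"]
        )
        assignment = sx.NodeAssignment(pd.Series([1], index=["g1"]), n_nodes=4)
        prof = sx.node_condition_means(
            assignment, sx.ExpressionMatrix(vals, "log2_normalized"), toy_metadata
        )
        assert prof.means.loc[1, ("AH", 1)] == pytest.approx(4.0)
        assert prof.folds.loc[1, ("AH", 2)] == pytest.approx(2.5)
        assert prof.member_count.loc[1] == 1

    def test_empty_node_flagged_undefined(self, toy_metadata):
        vals = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0]], index=["g1"], columns=["s1", "s2", "s3", "s4"]
        )
        assignment = sx.NodeAssignment(pd.Series([2], index=["g1"]), n_nodes=4)
        prof = sx.node_condition_means(
            assignment, sx.ExpressionMatrix(vals, "log2_normalized"), toy_metadata
        )
        assert prof.means.loc[3].isna().all()
        assert prof.member_count.loc[3] == 0

    def test_matches_brute_force_averaging(self, toy_metadata):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(12)]
        vals = pd.DataFrame(
            rng.normal(5, 2, size=(12, 4)), index=genes, columns=["s1", "s2", "s3", "s4"]
        )
        nodes = rng.integers(1, 5, size=12)
        assignment = sx.NodeAssignment(pd.Series(nodes, index=genes), n_nodes=4)
        prof = sx.node_condition_means(
            assignment, sx.ExpressionMatrix(vals, "log2_normalized"), toy_metadata
        )
        for node in range(1, 5):
            members = [g for g, n in zip(genes, nodes) if n == node]
            if not members:
                continue
            expected = np.mean(vals.loc[members, ["s1", "s2"]].to_numpy())
            assert prof.means.loc[node, ("AH", 1)] == pytest.approx(expected)

    def test_gene_order_within_nodes_irrelevant(self, pipeline):
        a = pipeline.assignment
        reversed_assignment = sx.NodeAssignment(a.gene_to_node.iloc[::-1], a.n_nodes)
        prof2 = sx.node_condition_means(
            reversed_assignment, pipeline.norm, pipeline.metadata
        )
        pd.testing.assert_frame_equal(pipeline.profiles.means, prof2.means)


class TestPercentileThreshold:
    def test_linear_interpolation_on_1_to_100(self):
        vals = pd.DataFrame(np.arange(1.0, 101.0).reshape(50, 2))
        em = sx.ExpressionMatrix(vals, "log2_normalized")
        assert sx.expression_percentile_threshold(em, 95) == pytest.approx(95.05)

    def test_constant_matrix(self):
        em = sx.ExpressionMatrix(pd.DataFrame(np.full((5, 4), 7.0)), "log2_normalized")
        assert sx.expression_percentile_threshold(em, 95) == 7.0

    def test_override_wins(self):
        em = sx.ExpressionMatrix(pd.DataFrame(np.zeros((3, 3))), "log2_normalized")
        assert sx.expression_percentile_threshold(em, 95, override=10.2) == 10.2


class TestConditionSpecificCalls:
    def test_mean_criterion_with_fixed_override(self):
        prof = _toy_profile()
        cfg = sx.NodeCallConfig(abs_threshold_override=10.2)
        calls = sx.call_condition_specific_nodes(prof, cfg)
        # node 2 (mean 10.5) flagged; node 3 sits exactly at 10.2 -> strict > excludes
        assert 2 in calls[("AH", 1)] and 3 not in calls[("AH", 1)]

    def test_fold_criterion_and_combine_semantics(self):
        prof = _toy_profile()
        any_calls = sx.call_condition_specific_nodes(
            prof, sx.NodeCallConfig(abs_threshold_override=10.2, combine="any")
        )
        all_calls = sx.call_condition_specific_nodes(
            prof, sx.NodeCallConfig(abs_threshold_override=10.2, combine="all")
        )
        # node 1: fold 2.5 > 2 but mean low -> flagged under any, not under all
        assert 1 in any_calls[("AH", 2)]
        assert 1 not in all_calls[("AH", 2)]

    def test_any_calls_superset_of_all_calls(self, pipeline):
        thr = sx.expression_percentile_threshold(pipeline.norm)
        any_calls = sx.call_condition_specific_nodes(
            pipeline.profiles, sx.NodeCallConfig(combine="any"), mean_threshold=thr
        )
        all_calls = sx.call_condition_specific_nodes(
            pipeline.profiles, sx.NodeCallConfig(combine="all"), mean_threshold=thr
        )
        for cond in any_calls:
            assert all_calls[cond] <= any_calls[cond]

    def test_empty_nodes_never_called(self):
        prof = _toy_profile()
        calls = sx.call_condition_specific_nodes(
            prof, sx.NodeCallConfig(abs_threshold_override=0.0)
        )
        assert 4 not in calls[("AH", 1)] and 4 not in calls[("AH", 2)]

    def test_reference_gp_only_mean_criterion(self):
        prof = _toy_profile()
        all_calls = sx.call_condition_specific_nodes(
            prof, sx.NodeCallConfig(abs_threshold_override=0.0, combine="all")
        )
        assert all_calls[("AH", 1)] == set()  # no fold exists at the reference

    def test_divergent_module_called_on_one_substrate_only(self, pipeline):
        truth = pipeline.truth
        div = [m for m, s in truth.module_shapes.items() if s == "substrate_divergent"][0]
        modal = pipeline.modal_node(div)
        assert modal in pipeline.calls[("AH", 5)]
        assert modal not in pipeline.calls[("WH", 5)]
        assert pipeline.profiles.folds.loc[modal, ("WH", 5)] < 0  # reversed on spruce


class TestHighExpression:
    def _cpm(self, values, genes):
        df = pd.DataFrame(values, index=genes, columns=["s1", "s2", "s3", "s4"])
        return sx.ExpressionMatrix(df.astype(float), "cpm")

    def test_toy_enumeration_and_strict_boundary(self, toy_metadata):
        # GP1 mean CPMs: 1, 10, 10, 10, 100 -> median 10, cut 25
        genes = ["a", "b", "c", "d", "e"]
        vals = [
            [1, 1, 1, 1],
            [10, 10, 10, 10],
            [10, 10, 10, 10],
            [10, 10, 10, 10],
            [100, 100, 25, 25],
        ]
        he = sx.high_expression_genes(self._cpm(vals, genes), toy_metadata)
        assert he.thresholds[("AH", 1)] == pytest.approx(25.0)
        assert he.per_condition[("AH", 1)] == {"e"}
        # at GP2 gene e sits exactly at the 25 cut -> excluded (strict)
        assert he.per_condition[("AH", 2)] == set()

    def test_pass_just_above_cut(self, toy_metadata):
        genes = ["a", "b", "c"]
        vals = [[10, 10, 10, 10], [26, 26, 26, 26], [1, 1, 1, 1]]
        he = sx.high_expression_genes(self._cpm(vals, genes), toy_metadata)
        assert "b" in he.per_condition[("AH", 1)]

    def test_scope_restriction_and_empty_scope_error(self, toy_metadata):
        genes = ["a", "b", "c"]
        vals = [[10, 10, 10, 10], [26, 26, 26, 26], [1, 1, 1, 1]]
        ann = sx.AnnotationTable(
            pd.DataFrame(
                [["a", "CAZy", "AA9"], ["b", "CAZy", "GH5"]],
                columns=["gene_id", "namespace", "label"],
            )
        )
        he = sx.high_expression_genes(
            self._cpm(vals, genes), toy_metadata, annotations=ann, scope="CAZy"
        )
        assert he.union <= {"a", "b"}
        with pytest.raises(sx.SomcoexError):
            sx.high_expression_genes(
                self._cpm(vals, genes), toy_metadata, annotations=ann, scope="P450_clan"
            )


class TestAnnotateNodes:
    def test_label_counts_per_node(self):
        assignment = sx.NodeAssignment(
            pd.Series([1, 1, 1], index=["g1", "g2", "g3"]), n_nodes=4
        )
        ann = sx.AnnotationTable(
            pd.DataFrame(
                [["g1", "CAZy", "AA9"], ["g2", "CAZy", "AA9"], ["g3", "CAZy", "GH5"]],
                columns=["gene_id", "namespace", "label"],
            )
        )
        out = sx.annotate_nodes(assignment, ann)
        counts = out.set_index("label")["count"]
        assert counts["AA9"] == 2 and counts["GH5"] == 1

    def test_unannotated_gene_counted(self):
        assignment = sx.NodeAssignment(pd.Series([2], index=["gX"]), n_nodes=4)
        ann = sx.AnnotationTable(
            pd.DataFrame([["other", "CAZy", "AA9"]], columns=["gene_id", "namespace", "label"])
        )
        out = sx.annotate_nodes(assignment, ann)
        row = out[(out["node_id"] == 2) & (out["namespace"] == "unannotated")]
        assert row["count"].iloc[0] == 1

    def test_cooccurrence_query(self):
        assignment = sx.NodeAssignment(
            pd.Series([1, 1, 2], index=["g1", "g2", "g3"]), n_nodes=2
        )
        ann = sx.AnnotationTable(
            pd.DataFrame(
                [
                    ["g1", "P450_clan", "CYP52"],
                    ["g2", "CAZy", "AA9"],
                    ["g3", "P450_clan", "CYP64"],
                ],
                columns=["gene_id", "namespace", "label"],
            )
        )
        out = sx.annotate_nodes(assignment, ann)
        both = sx.nodes_containing(out, "P450_clan") & sx.nodes_containing(out, "CAZy")
        assert both == {1}

    def test_module_family_enriched_in_called_nodes(self, pipeline):
        # module_1 ("rising", labelled AA2) peaks at GP5 on both substrates;
        # its family should be enriched in the (AH, GP5)-called node set
        out = sx.annotate_nodes(pipeline.assignment, pipeline.annotations)
        called = pipeline.calls[("AH", 5)]
        gene_nodes = pipeline.assignment.gene_to_node
        in_called = gene_nodes.isin(list(called))
        fam_genes = set(pipeline.annotations.genes_with("CAZy", "AA2")) & set(gene_nodes.index)
        n_pop = len(gene_nodes)
        n_fam = len(fam_genes)
        n_draw = int(in_called.sum())
        k = sum(in_called.loc[g] for g in fam_genes)
        p = hypergeom.sf(k - 1, n_pop, n_fam, n_draw)
        assert p < 0.01


class TestRenderTatami:
    def test_writes_single_panel_grid(self, tmp_path):
        prof = _toy_profile()
        calls = {("AH", 1): {3}, ("AH", 2): set()}
        out = sx.render_tatami(prof, calls, rows=2, cols=2, path=tmp_path / "t.png")
        assert out.exists() and out.stat().st_size > 0

    def test_default_run_renders_ten_panels(self, pipeline, tmp_path):
        out = sx.render_tatami(
            pipeline.profiles,
            pipeline.calls,
            rows=24,
            cols=20,
            path=tmp_path / "tatami.png",
            label_nodes=False,
        )
        assert out.exists()
        assert len(pipeline.profiles.means.columns) == 10
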