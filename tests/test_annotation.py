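import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathprs import (
    AnnotationSources,
    build_gene_pathway_weights,
    build_variant_gene_weights,
    build_variant_pathway_weights,
    combine_mappings,
    mapping_summary,
    PATHWAYS,
    UNMAPPED,
)
from pathprs.annotation import (
    VariantGeneWeights,
    GenePathwayWeights,
    read_variant_pathway_weights,
    write_variant_pathway_weights,
)
from pathprs.datatypes import AnnotationError


def vg_df(pairs):
    return pd.DataFrame(pairs, columns=["variant_id", "gene"])


def gp_df(pairs):
    return pd.DataFrame(pairs, columns=["gene", "pathway"])


def sources(vg1=(), vg2=(), gp=None, fixed=None):
    gp_lists = gp or {
        "magma": gp_df([]), "go": gp_df([]), "david": gp_df([]), "review": gp_df([]),
    }
    return AnnotationSources(
        {"study1": vg_df(list(vg1)), "study2": vg_df(list(vg2))},
        gp_lists,
        fixed or {},
    )


class TestVariantGeneWeights:
    def test_counts_across_two_studies(self):
        src = sources(vg1=[("rs1", "A"), ("rs1", "B")], vg2=[("rs1", "A")])
        w = build_variant_gene_weights(src).weights["rs1"]
        assert w == {"A": pytest.approx(2 / 3), "B": pytest.approx(1 / 3)}

    def test_single_list_single_gene(self):
        src = sources(vg1=[("rs1", "A")])
        assert build_variant_gene_weights(src).weights["rs1"] == {"A": 1.0}

    def test_fixed_gene_overrides_conflicting_lists(self):
        src = sources(
            vg1=[("rs1", "A"), ("rs1", "B")],
            vg2=[("rs1", "C")],
            fixed={"rs1": "APOE"},
        )
        assert build_variant_gene_weights(src).weights["rs1"] == {"APOE": 1.0}

    def test_within_source_duplicates_count_once(self):
        src = sources(vg1=[("rs1", "A"), ("rs1", "A"), ("rs1", "B")])
        w = build_variant_gene_weights(src).weights["rs1"]
        assert w == {"A": pytest.approx(0.5), "B": pytest.approx(0.5)}

    def test_gene_matching_case_insensitive(self):
        src = sources(vg1=[("rs1", "abc")], vg2=[("rs1", "ABC")])
        assert build_variant_gene_weights(src).weights["rs1"] == {"ABC": 1.0}


class TestGenePathwayWeights:
    def test_counts_across_sources(self):
        gp = {
            "magma": gp_df([("G1", "immune_response")]),
            "go": gp_df([("G1", "immune_response"), ("G1", "endocytosis")]),
            "david": gp_df([]),
            "review": gp_df([]),
        }
        src = sources(vg1=[("rs1", "G1")], gp=gp)
        w = build_gene_pathway_weights(src, {"G1"}).weights["G1"]
        assert w["immune_response"] == pytest.approx(2 / 3)
        assert w["endocytosis"] == pytest.approx(1 / 3)

    def test_single_association(self):
        gp = {"review": gp_df([("G1", "angiogenesis")])}
        src = sources(vg1=[("rs1", "G1")], gp=gp)
        assert build_gene_pathway_weights(src, {"G1"}).weights["G1"] == {
            "angiogenesis": 1.0
        }

    def test_absent_gene_is_unmapped(self):
        gp = {"review": gp_df([("G1", "angiogenesis")])}
        src = sources(vg1=[("rs1", "G1"), ("rs1", "G2")], gp=gp)
        out = build_gene_pathway_weights(src, {"G1", "G2"})
        assert out.unmapped_genes == frozenset({"G2"})

    def test_unknown_pathway_rejected_naming_source(self):
        gp = {"review": gp_df([("G1", "telepathy")])}
        with pytest.raises(AnnotationError, match="review"):
            sources(vg1=[("rs1", "G1")], gp=gp)


class TestCombine:
    def test_single_fully_mapped_gene(self):
        vg = VariantGeneWeights({"rs1": {"G1": 1.0}})
        gp = GenePathwayWeights({"G1": {"endocytosis": 1.0}})
        row = combine_mappings(vg, gp).weights["rs1"]
        assert row["endocytosis"] == 1.0
        assert row[UNMAPPED] == 0.0

    def test_partial_unmapped_residual(self):
        vg = VariantGeneWeights({"rs1": {"A": 0.5, "B": 0.5}})
        gp = GenePathwayWeights({"A": {"immune_response": 1.0}}, frozenset({"B"}))
        row = combine_mappings(vg, gp).weights["rs1"]
        assert row["immune_response"] == pytest.approx(0.5)
        assert row[UNMAPPED] == pytest.approx(0.5)

    def test_all_genes_unmapped(self):
        vg = VariantGeneWeights({"rs1": {"A": 0.6, "B": 0.4}})
        gp = GenePathwayWeights({}, frozenset({"A", "B"}))
        assert combine_mappings(vg, gp).weights["rs1"][UNMAPPED] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_conservation_for_random_lists(self, data):
        """Sum over pathways + unmapped is exactly 1 for any input lists."""
        variants = [f"rs{i}" for i in range(1, 5)]
        genes = [f"G{i}" for i in range(6)]
        vg1 = data.draw(
            st.lists(st.tuples(st.sampled_from(variants), st.sampled_from(genes)),
                     min_size=1, max_size=12)
        )
        vg2 = data.draw(
            st.lists(st.tuples(st.sampled_from(variants), st.sampled_from(genes)),
                     max_size=12)
        )
        gp_pairs = data.draw(
            st.lists(st.tuples(st.sampled_from(genes), st.sampled_from(PATHWAYS)),
                     max_size=15)
        )
        src = sources(vg1=vg1, vg2=vg2, gp={"magma": gp_df(gp_pairs)})
        vpw, _ = build_variant_pathway_weights(src)
        for row in vpw.weights.values():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_recount(self):
        """Random small annotation sets agree with an independent recount."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            variants = [f"rs{i}" for i in range(rng.integers(2, 10))]
            genes = [f"G{i}" for i in range(rng.integers(2, 20))]
            vg_lists = {
                name: [
                    (rng.choice(variants), rng.choice(genes))
                    for _ in range(rng.integers(1, 15))
                ]
                for name in ("study1", "study2")
            }
            gp_lists = {
                name: [
                    (rng.choice(genes), rng.choice(PATHWAYS))
                    for _ in range(rng.integers(0, 10))
                ]
                for name in ("magma", "go", "david", "review")
            }
            src = sources(
                vg1=vg_lists["study1"], vg2=vg_lists["study2"],
                gp={k: gp_df(v) for k, v in gp_lists.items()},
            )
            vpw, _ = build_variant_pathway_weights(src)
            expected = brute_force_weights(vg_lists, gp_lists)
            for vid, row in expected.items():
                for p in (*PATHWAYS, UNMAPPED):
                    assert vpw.weights[vid][p] == pytest.approx(
                        row[p], abs=1e-12
                    ), (vid, p)


def brute_force_weights(vg_lists, gp_lists):
    """Independent oracle: recount weights by direct enumeration."""
    vg_counts = {}
    for pairs in vg_lists.values():
        for pair in set(pairs):
            vg_counts.setdefault(pair[0], []).append(pair[1])
    gp_counts = {}
    for pairs in gp_lists.values():
        for pair in set(pairs):
            gp_counts.setdefault(pair[0], []).append(pair[1])
    out = {}
    for vid, gene_hits in vg_counts.items():
        row = {p: 0.0 for p in (*PATHWAYS, UNMAPPED)}
        for gene in set(gene_hits):
            m = gene_hits.count(gene) / len(gene_hits)
            if gene in gp_counts:
                hits = gp_counts[gene]
                for p in set(hits):
                    row[p] += m * hits.count(p) / len(hits)
            else:
                row[UNMAPPED] += m
        out[vid] = row
    return out


class TestSummaryAndIO:
    def test_summary_counts_positive_weight_variants(self):
        src = sources(
            vg1=[("rs1", "G1"), ("rs2", "G1"), ("rs3", "G9")],
            gp={"magma": gp_df([("G1", "immune_response")])},
        )
        vpw, summary = build_variant_pathway_weights(src)
        assert summary["variants_per_pathway"]["immune_response"] == 2
        assert summary["n_mapped_loci"] == 2
        assert summary["n_fully_unmapped_variants"] == 1
        assert summary["n_variant_linked_genes"] == 2
        assert summary["n_pathway_mapped_genes"] == 1

    def test_empty_mapping_all_zero(self):
        vpw = combine_mappings(
            VariantGeneWeights({}), GenePathwayWeights({}, frozenset())
        )
        summary = mapping_summary(vpw)
        assert summary["n_variants"] == 0
        assert all(v == 0 for v in summary["variants_per_pathway"].values())

    def test_weights_tsv_round_trip(self, true_weights, tmp_path):
        path = tmp_path / "w.tsv"
        write_variant_pathway_weights(true_weights, path)
        back = read_variant_pathway_weights(path)
        a = true_weights.to_frame()
        b = back.to_frame().loc[a.index, a.columns]
        np.testing.assert_allclose(b.to_numpy(), a.to_numpy(), atol=1e-10)

    def test_default_mapping_summary(self, true_weights, panel):
        vpw = true_weights.complete(panel.variant_ids)
        summary = mapping_summary(vpw)
        assert summary["n_variants"] == 29
        assert summary["n_mapped_loci"] + summary["n_fully_unmapped_variants"] == 29
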