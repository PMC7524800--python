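import numpy as np
import pandas as pd
import pytest

from pathprs import (
    compute_pathway_prs,
    compute_prs,
    scale_scores,
    UNMAPPED,
)
from pathprs.annotation import VariantPathwayWeights
from pathprs.datatypes import MissingDataError, ScoreError
from pathprs.scores import read_scores, write_scores

from conftest import make_dosages, make_phenotypes, make_variants


def full_weight(pathway):
    return {pathway: 1.0}


class TestComputePrs:
    def test_single_variant(self):
        vt = make_variants([("rs1", 0.1, 0.2, False)])
        dm = make_dosages(["s"], ["rs1"], [[2.0]])
        assert compute_prs(dm, vt).loc["s"] == pytest.approx(0.2)

    def test_all_zero_dosages(self):
        vt = make_variants([("rs1", 0.1, 0.2, False), ("rs2", -0.5, 0.3, False)])
        dm = make_dosages(["s"], ["rs1", "rs2"], [[0.0, 0.0]])
        assert compute_prs(dm, vt).loc["s"] == 0.0

    def test_hand_sum(self):
        vt = make_variants(
            [("rs1", 0.2, 0.2, False), ("rs2", -0.1, 0.2, False), ("rs3", 0.05, 0.2, False)]
        )
        dm = make_dosages(["s"], ["rs1", "rs2", "rs3"], [[1.0, 2.0, 0.0]])
        assert compute_prs(dm, vt).loc["s"] == pytest.approx(0.0)

    def test_apoe_exclusion(self):
        vt = make_variants([("rs1", 0.1, 0.2, False), ("rsE", 1.0, 0.2, True)])
        dm = make_dosages(["s"], ["rs1", "rsE"], [[1.0, 2.0]])
        assert compute_prs(dm, vt, exclude_apoe=False).loc["s"] == pytest.approx(2.1)
        assert compute_prs(dm, vt, exclude_apoe=True).loc["s"] == pytest.approx(0.1)

    def test_missing_variant_errors_with_ids(self):
        vt = make_variants([("rs1", 0.1, 0.2, False), ("rs2", 0.1, 0.2, False)])
        dm = make_dosages(["s"], ["rs1"], [[1.0]])
        with pytest.raises(MissingDataError, match="rs2"):
            compute_prs(dm, vt)

    def test_positive_allele_strictly_increases_score(self):
        vt = make_variants([("rs1", 0.3, 0.2, False)])
        low = make_dosages(["s"], ["rs1"], [[1.0]])
        high = make_dosages(["s"], ["rs1"], [[2.0]])
        assert compute_prs(high, vt).loc["s"] > compute_prs(low, vt).loc["s"]


class TestPathwayPrs:
    def test_fully_mapped_variant(self):
        vt = make_variants([("rs1", 0.1, 0.2, False)])
        vpw = VariantPathwayWeights({"rs1": full_weight("endocytosis")})
        dm = make_dosages(["s"], ["rs1"], [[1.0]])
        sm = compute_pathway_prs(dm, vt, vpw)
        assert sm.raw.loc["s", "endocytosis"] == pytest.approx(0.1)
        assert sm.raw.loc["s", "immune_response"] == 0.0

    def test_split_weights(self):
        vt = make_variants([("rs1", 0.1, 0.2, False)])
        vpw = VariantPathwayWeights(
            {"rs1": {"immune_response": 0.6, "endocytosis": 0.4}}
        )
        dm = make_dosages(["s"], ["rs1"], [[2.0]])
        sm = compute_pathway_prs(dm, vt, vpw)
        assert sm.raw.loc["s", "immune_response"] == pytest.approx(0.12)
        assert sm.raw.loc["s", "endocytosis"] == pytest.approx(0.08)

    def test_unmapped_variant_contributes_only_unmapped(self):
        vt = make_variants([("rs1", 0.1, 0.2, False)])
        vpw = VariantPathwayWeights({"rs1": {UNMAPPED: 1.0}})
        dm = make_dosages(["s"], ["rs1"], [[2.0]])
        sm = compute_pathway_prs(dm, vt, vpw)
        assert sm.raw.loc["s", UNMAPPED] == pytest.approx(0.2)
        assert sm.raw.loc["s", "immune_response"] == 0.0

    def test_missing_weight_row_errors(self):
        vt = make_variants([("rs1", 0.1, 0.2, False), ("rs2", 0.1, 0.2, False)])
        vpw = VariantPathwayWeights({"rs1": full_weight("endocytosis")})
        dm = make_dosages(["s"], ["rs1", "rs2"], [[1.0, 1.0]])
        with pytest.raises(ScoreError, match="rs2"):
            compute_pathway_prs(dm, vt, vpw)

    def test_additivity_random_instances(self):
        """Pathway + unmapped scores reconstruct the PRS for random mappings."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = int(rng.integers(1, 8))
            n = int(rng.integers(1, 12))
            vt = make_variants(
                [(f"rs{i}", float(rng.normal(0, 0.3)), 0.2, False) for i in range(k)]
            )
            weights = {}
            for i in range(k):
                w = rng.dirichlet(np.ones(6))
                weights[f"rs{i}"] = dict(
                    zip(("immune_response", "beta_amyloid", "endocytosis",
                         "cholesterol_lipid", "angiogenesis", UNMAPPED), w)
                )
            vpw = VariantPathwayWeights(weights)
            dm = make_dosages(
                [f"s{j}" for j in range(n)],
                [f"rs{i}" for i in range(k)],
                rng.uniform(0, 2, size=(n, k)),
            )
            sm = compute_pathway_prs(dm, vt, vpw)
            recon = sm.raw.drop(columns="PRS").sum(axis=1)
            np.testing.assert_allclose(recon, sm.raw["PRS"], atol=1e-9)

    def test_effect_allele_flip_leaves_scaled_scores(self):
        """Recoding dosage -> 2-dosage with beta -> -beta shifts raw scores
        by a constant and leaves the z-scaled scores unchanged."""
        rng = np.random.default_rng(4)
        n = 40
        dos = rng.integers(0, 3, size=(n, 2)).astype(float)
        subj = [f"s{i}" for i in range(n)]
        phe = make_phenotypes(subj, ["P"] * (n // 2) + ["A"] * (n // 2))
        vpw = VariantPathwayWeights(
            {"rs0": full_weight("immune_response"), "rs1": full_weight("endocytosis")}
        )
        vt = make_variants([("rs0", 0.2, 0.2, False), ("rs1", -0.1, 0.3, False)])
        sm = scale_scores(
            compute_pathway_prs(make_dosages(subj, ["rs0", "rs1"], dos), vt, vpw),
            phe, on_constant="drop",
        )
        flipped_dos = dos.copy()
        flipped_dos[:, 0] = 2.0 - flipped_dos[:, 0]
        vt_flip = make_variants([("rs0", -0.2, 0.2, False), ("rs1", -0.1, 0.3, False)])
        sm_flip = scale_scores(
            compute_pathway_prs(
                make_dosages(subj, ["rs0", "rs1"], flipped_dos), vt_flip, vpw
            ),
            phe, on_constant="drop",
        )
        diff = sm_flip.raw["PRS"] - sm.raw["PRS"]
        assert diff.std() == pytest.approx(0.0, abs=1e-12)  # constant shift
        pd.testing.assert_frame_equal(sm.scaled, sm_flip.scaled, atol=1e-9, rtol=0)


class TestScaling:
    def test_hand_example(self):
        vt = make_variants([("rs1", 1.0, 0.2, False)])
        vpw = VariantPathwayWeights({"rs1": full_weight("immune_response")})
        dm = make_dosages(["a", "b", "c"], ["rs1"], [[1.0], [2.0], [0.0]])
        phe = make_phenotypes(["a", "b", "c"], ["P", "A", "C"])
        sm = scale_scores(compute_pathway_prs(dm, vt, vpw), phe, columns=["PRS"])
        # raw (1,2,0): mean 1, sample SD 1 -> z = (0,1,-1)
        np.testing.assert_allclose(sm.scaled["PRS"], [0.0, 1.0, -1.0], atol=1e-12)

    def test_scaled_columns_standardised_over_pool(self, small_study, panel, true_weights):
        _, sim = small_study
        vpw = true_weights.complete(panel.variant_ids)
        sm = scale_scores(
            compute_pathway_prs(sim.dosages, panel, vpw), sim.phenotypes
        )
        for col in sm.scaled.columns:
            assert sm.scaled[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert sm.scaled[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_idempotence(self):
        vt = make_variants([("rs1", 1.0, 0.2, False)])
        vpw = VariantPathwayWeights({"rs1": full_weight("immune_response")})
        dm = make_dosages(["a", "b", "c"], ["rs1"], [[1.0], [2.0], [0.0]])
        phe = make_phenotypes(["a", "b", "c"], ["P", "A", "C"])
        once = scale_scores(compute_pathway_prs(dm, vt, vpw), phe, columns=["PRS"])
        from pathprs.scores import ScoreMatrix

        again = scale_scores(
            ScoreMatrix(once.subject_ids, once.scaled, True, {}), phe, columns=["PRS"]
        )
        np.testing.assert_allclose(
            again.scaled["PRS"], once.scaled["PRS"], atol=1e-9
        )

    def test_constant_column_errors(self):
        vt = make_variants([("rs1", 1.0, 0.2, False)])
        vpw = VariantPathwayWeights({"rs1": full_weight("immune_response")})
        dm = make_dosages(["a", "b"], ["rs1"], [[1.0], [1.0]])
        phe = make_phenotypes(["a", "b"], ["P", "A"])
        with pytest.raises(ScoreError, match="PRS"):
            scale_scores(compute_pathway_prs(dm, vt, vpw), phe, columns=["PRS"])

    def test_apoe_modes_rescale_from_scratch(self, small_study, panel, true_weights):
        _, sim = small_study
        vpw = true_weights.complete(panel.variant_ids)
        with_apoe = scale_scores(
            compute_pathway_prs(sim.dosages, panel, vpw), sim.phenotypes,
            on_constant="drop",
        )
        without = scale_scores(
            compute_pathway_prs(sim.dosages, panel, vpw, exclude_apoe=True),
            sim.phenotypes, on_constant="drop",
        )
        assert with_apoe.scaling["PRS"] != without.scaling["PRS"]
        assert without.scaled["PRS"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_scores_tsv_round_trip(tmp_path):
    vt = make_variants([("rs1", 1.0, 0.2, False)])
    vpw = VariantPathwayWeights({"rs1": full_weight("immune_response")})
    dm = make_dosages(["a", "b", "c"], ["rs1"], [[1.0], [2.0], [0.0]])
    phe = make_phenotypes(["a", "b", "c"], ["P", "A", "C"])
    sm = scale_scores(compute_pathway_prs(dm, vt, vpw), phe, columns=["PRS"])
    write_scores(sm, tmp_path / "s.tsv", tmp_path / "s.json")
    back = read_scores(tmp_path / "s.tsv")
    np.testing.assert_allclose(back.raw["PRS"], sm.raw["PRS"], atol=1e-12)
    np.testing.assert_allclose(back.scaled["PRS"], sm.scaled["PRS"], atol=1e-12)
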