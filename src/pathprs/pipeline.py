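"""End-to-end orchestration: map -> score -> associate -> contrast -> contribute.

`run_full_analysis` is the single entry point behind the ``run-all``
command and the reproduction script: given harmonised dosages, phenotypes,
a variant panel and a variant-pathway mapping, it computes both APOE modes
of the (p)PRS, fits the association panel, forms the resilience/risk
effect ratios with sampled CIs, compares the ratios across APOE modes, and
decomposes the polygenic variance into pathway shares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation import VariantPathwayWeights
from .association import (
    AssociationResult,
    fit_score_association,
    run_association_panel,
)
from .datatypes import DosageMatrix, PhenotypeTable, VariantTable, PATHWAYS, PRS_COLUMN
from .io import estimate_maf, fill_missing, match_subjects
from .resilience import (
    EffectRatio,
    RatioComparison,
    compare_ratios,
    sample_ratio_ci,
)
from .scores import ScoreMatrix, compute_pathway_prs, scale_scores
from .variance import ContributionTable, pathway_contribution

logger = logging.getLogger("pathprs")


@dataclass
class AnalysisResult:
    """Everything one full run produces."""

    scores: dict[bool, ScoreMatrix]
    associations: list[AssociationResult]
    association_errors: list[dict]
    ratios: list[EffectRatio]
    ratio_comparisons: list[RatioComparison]
    contributions: dict[bool, ContributionTable]
    maf_estimate: "object" = None
    seed: int = 0

    def association(
        self, comparison: str, score_name: str, apoe_included: bool, stratum: str = "all"
    ) -> AssociationResult:
        for r in self.associations:
            if (
                r.comparison == comparison
                and r.score_name == score_name
                and r.apoe_included == apoe_included
                and r.stratum == stratum
            ):
                return r
        raise KeyError((comparison, score_name, apoe_included, stratum))


def run_full_analysis(
    dosages: DosageMatrix,
    phenotypes: PhenotypeTable,
    variants: VariantTable,
    vpw: VariantPathwayWeights,
    n_draws: int = 10_000,
    seed: int = 0,
    estimate_maf_from_population: bool = True,
) -> AnalysisResult:
    """Run the complete analysis in both APOE modes."""
    dosages, phenotypes = match_subjects(dosages, phenotypes)
    maf_frame = None
    if estimate_maf_from_population:
        maf_frame = estimate_maf(dosages, phenotypes, cohort="P")
        variants = variants.with_maf(maf_frame["maf"])
    dosages = fill_missing(dosages, variants)
    vpw = vpw.complete(variants.variant_ids)

    scores: dict[bool, ScoreMatrix] = {}
    for apoe_included in (True, False):
        raw = compute_pathway_prs(
            dosages, variants, vpw, exclude_apoe=not apoe_included
        )
        scores[apoe_included] = scale_scores(raw, phenotypes, on_constant="drop")

    associations, errors = run_association_panel(scores, phenotypes)

    ratios: list[EffectRatio] = []
    comparisons: list[RatioComparison] = []
    rng = np.random.default_rng(seed)
    score_names = [PRS_COLUMN, *PATHWAYS]
    for score_name in score_names:
        per_mode: dict[bool, EffectRatio] = {}
        for apoe_included in (True, False):
            try:
                risk = _find(associations, "A_vs_P", score_name, apoe_included)
                res = _find(associations, "C_vs_P", score_name, apoe_included)
                per_mode[apoe_included] = sample_ratio_ci(
                    risk, res, n_draws=n_draws, seed=int(rng.integers(2**31 - 1))
                )
            except Exception as exc:  # cell failed upstream
                logger.warning("ratio for %s (apoe=%s) unavailable: %s",
                               score_name, apoe_included, exc)
        ratios.extend(per_mode.values())
        if True in per_mode and False in per_mode:
            comparisons.append(compare_ratios(per_mode[True], per_mode[False]))

    contributions = {
        True: pathway_contribution(variants, vpw, exclude_apoe=False),
        False: pathway_contribution(variants, vpw, exclude_apoe=True),
    }
    return AnalysisResult(
        scores=scores,
        associations=associations,
        association_errors=errors,
        ratios=ratios,
        ratio_comparisons=comparisons,
        contributions=contributions,
        maf_estimate=maf_frame,
        seed=seed,
    )


def _find(
    results: list[AssociationResult], comparison: str, score_name: str, apoe_included: bool
) -> AssociationResult:
    for r in results:
        if (
            r.comparison == comparison
            and r.score_name == score_name
            and r.apoe_included == apoe_included
            and r.stratum == "all"
        ):
            return r
    raise KeyError((comparison, score_name, apoe_included))
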