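"""Decomposition of total polygenic risk variance into pathway shares.

Treating variants as independent, the variance of the PRS is
``sum_k beta_k^2 * Var(dos_k)``, and each pathway's share weights every
variant's term by its variant-pathway probability ``M_p^k``:

    P^p = sum_k M_p^k * beta_k^2 * MAF_k * (1 - MAF_k)
          -----------------------------------------------
          sum_k         beta_k^2 * MAF_k * (1 - MAF_k)

expressed as a percentage. The Bernoulli form ``MAF (1 - MAF)`` is used as
printed; a diploid dosage variance ``2 MAF (1 - MAF)`` differs by a
constant that cancels in the ratio. Because each variant's weights
(including the reserved ``unmapped`` category, set to 1 for variants with
no mapping) sum to one, the shares sum to exactly 100% and the
pathway-PRS variances sum to the total PRS variance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import VariantPathwayWeights
from .datatypes import MissingDataError, ScoreError, UNMAPPED, VariantTable

logger = logging.getLogger("pathprs")


@dataclass
class ContributionTable:
    """Percentage of polygenic risk variance per pathway (plus unmapped)."""

    apoe_included: bool
    percentages: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"contributions sum to {total}, expected 100")

    @property
    def largest(self) -> str:
        return max(self.percentages, key=self.percentages.get)

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {p: round(v, ndigits) for p, v in self.percentages.items()}


def pathway_contribution(
    variants: VariantTable,
    vpw: VariantPathwayWeights,
    exclude_apoe: bool = False,
    maf: pd.Series | None = None,
) -> ContributionTable:
    """Evaluate the variance-share formula over the (possibly APOE-free) panel.

    ``maf`` overrides the panel's stored allele frequencies (e.g. reference
    frequencies instead of the population-cohort estimate). Variants with
    MAF 0 or 1 contribute zero variance (warning); a missing MAF is an
    error. Variants without a weight row count as fully unmapped.
    """
    panel = variants.without_apoe() if exclude_apoe else variants
    if len(panel) == 0:
        raise MissingDataError("no variants left after APOE exclusion")
    mafs = panel.maf if maf is None else maf.reindex(panel.variant_ids)
    missing = [v for v in panel.variant_ids if not np.isfinite(mafs.get(v, np.nan))]
    if missing:
        raise MissingDataError(f"MAF missing for {missing}")
    degenerate = [v for v in panel.variant_ids if mafs[v] in (0.0, 1.0)]
    if degenerate:
        logger.warning("variants with MAF 0 or 1 contribute no variance: %s", degenerate)
    weights = vpw.complete(panel.variant_ids).weights
    cols = [*vpw.pathways, UNMAPPED]
    beta = panel.beta
    num = {p: 0.0 for p in cols}
    denom = 0.0
    for vid in panel.variant_ids:
        term = beta[vid] ** 2 * mafs[vid] * (1.0 - mafs[vid])
        denom += term
        for p in cols:
            num[p] += weights[vid].get(p, 0.0) * term
    if denom <= 0.0:
        raise ScoreError("total polygenic variance is zero; cannot decompose")
    pct = {p: float(100.0 * num[p] / denom) for p in cols}
    # exact renormalisation guards against accumulated float error
    total = sum(pct.values())
    pct = {p: float(v * (100.0 / total)) for p, v in pct.items()}
    return ContributionTable(apoe_included=not exclude_apoe, percentages=pct)


def contribution_report(
    with_apoe: ContributionTable, without_apoe: ContributionTable
) -> dict:
    """Side-by-side serialisation of both APOE modes with argmax labels."""
    return {
        "with_apoe": {
            "percentages": with_apoe.percentages,
            "rounded": with_apoe.rounded(),
            "largest": with_apoe.largest,
        },
        "without_apoe": {
            "percentages": without_apoe.percentages,
            "rounded": without_apoe.rounded(),
            "largest": without_apoe.largest,
        },
    }


def write_contributions(
    with_apoe: ContributionTable,
    without_apoe: ContributionTable,
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "with_apoe": pd.Series(with_apoe.percentages),
            "without_apoe": pd.Series(without_apoe.percentages),
        }
    ).rename_axis("pathway")
    df.to_csv(tsv_path, sep="\t", float_format="%.12g")
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(contribution_report(with_apoe, without_apoe), indent=2)
        )
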