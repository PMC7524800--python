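"""Polygenic risk scores, total and pathway-partitioned.

The total score of subject ``s`` is ``PRS^s = sum_k dos_k^s * beta_k`` over
the variant panel; the pathway score adds the variant-pathway weight as a
multiplicative factor, ``pPRS_p^s = sum_k dos_k^s * beta_k * M_p^k``.
Because each variant's weights (including the reserved ``unmapped``
category) sum to one, the pathway scores plus the unmapped score
reconstruct the total PRS exactly.

Scores are z-scaled (mean 0, SD 1, sample SD with n-1) over the pooled
population + case + centenarian subjects, so logistic effect sizes read as
odds ratios per one SD of score. The APOE-exclusion mode recomputes and
rescales from scratch — scaling is nonlinear in the variant set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import VariantPathwayWeights
from .datatypes import (
    DosageMatrix,
    MissingDataError,
    PhenotypeTable,
    ScoreError,
    VariantTable,
    PRS_COLUMN,
    UNMAPPED,
)

logger = logging.getLogger("pathprs")


@dataclass
class ScoreMatrix:
    """Per-subject total PRS and per-pathway pPRS, raw and z-scaled."""

    subject_ids: list[str]
    raw: pd.DataFrame
    apoe_included: bool
    variant_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    scaled: pd.DataFrame | None = None
    #: per-column (mean, sd) used for scaling, on the pooled population
    scaling: dict[str, tuple[float, float]] | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.raw.columns)

    def column(self, name: str, scaled: bool = True) -> pd.Series:
        frame = self.scaled if scaled else self.raw
        if scaled and frame is None:
            raise ScoreError("scores have not been scaled yet")
        if name not in frame.columns:
            raise ScoreError(f"unknown score column {name!r}")
        return frame[name]


def _included_variants(
    variants: VariantTable, dosages: DosageMatrix, exclude_apoe: bool
) -> VariantTable:
    panel = variants.without_apoe() if exclude_apoe else variants
    have = set(dosages.variant_ids)
    absent = [v for v in panel.variant_ids if v not in have]
    if absent:
        raise MissingDataError(f"panel variants absent from dosages: {absent}")
    return panel


def compute_prs(
    dosages: DosageMatrix, variants: VariantTable, exclude_apoe: bool = False
) -> pd.Series:
    """Total PRS per subject: dosage-weighted sum of published log-ORs."""
    panel = _included_variants(variants, dosages, exclude_apoe)
    dos = dosages.subset_variants(panel.variant_ids)
    if dos.missing.any():
        raise ScoreError("fill missing dosages before scoring")
    beta = panel.beta.loc[dos.variant_ids].to_numpy()
    return pd.Series(dos.dosages @ beta, index=dosages.subject_ids, name=PRS_COLUMN)


def compute_pathway_prs(
    dosages: DosageMatrix,
    variants: VariantTable,
    vpw: VariantPathwayWeights,
    exclude_apoe: bool = False,
) -> ScoreMatrix:
    """Total PRS plus one pPRS column per pathway (and ``unmapped``)."""
    panel = _included_variants(variants, dosages, exclude_apoe)
    missing_rows = [v for v in panel.variant_ids if v not in vpw.weights]
    if missing_rows:
        raise ScoreError(
            f"variant-pathway weight rows missing for {missing_rows}; "
            "use VariantPathwayWeights.complete() for fully unmapped variants"
        )
    dos = dosages.subset_variants(panel.variant_ids)
    if dos.missing.any():
        raise ScoreError("fill missing dosages before scoring")
    beta = panel.beta.loc[dos.variant_ids].to_numpy()
    cols = [*vpw.pathways, UNMAPPED]
    weight_mat = np.array(
        [[vpw.weights[v].get(p, 0.0) for p in cols] for v in dos.variant_ids]
    )
    weighted = dos.dosages * beta  # subjects x variants
    raw = pd.DataFrame(weighted @ weight_mat, index=dos.subject_ids, columns=cols)
    raw.insert(0, PRS_COLUMN, weighted.sum(axis=1))
    sets = {PRS_COLUMN: tuple(dos.variant_ids)}
    for j, p in enumerate(cols):
        sets[p] = tuple(
            v for i, v in enumerate(dos.variant_ids) if weight_mat[i, j] > 0.0
        )
    return ScoreMatrix(list(dos.subject_ids), raw, not exclude_apoe, sets)


def scale_scores(
    scores: ScoreMatrix,
    phenotypes: PhenotypeTable,
    columns: list[str] | None = None,
    on_constant: str = "error",
) -> ScoreMatrix:
    """Z-scale each column over the pooled three-cohort population.

    Scaling constants (mean, sample SD) are computed over all subjects
    present in the phenotype table and applied to every subject. A
    zero-variance column raises :class:`ScoreError` naming the column,
    unless ``on_constant="drop"`` (the pipeline drops an all-zero
    ``unmapped`` column this way, with a log message).
    """
    if on_constant not in ("error", "drop"):
        raise ValueError("on_constant must be 'error' or 'drop'")
    pool = [s for s in scores.subject_ids if s in set(phenotypes.subject_ids)]
    if len(pool) < 2:
        raise ScoreError("need at least 2 pooled subjects to scale")
    columns = list(scores.raw.columns) if columns is None else columns
    pooled = scores.raw.loc[pool]
    scaled = {}
    constants: dict[str, tuple[float, float]] = {}
    for col in columns:
        mean = float(pooled[col].mean())
        sd = float(pooled[col].std(ddof=1))
        if not np.isfinite(sd) or sd <= 0.0:
            if on_constant == "drop":
                logger.warning("dropping zero-variance score column %r", col)
                continue
            raise ScoreError(f"score column {col!r} has zero variance")
        scaled[col] = (scores.raw[col] - mean) / sd
        constants[col] = (mean, sd)
    return ScoreMatrix(
        scores.subject_ids,
        scores.raw,
        scores.apoe_included,
        scores.variant_sets,
        scaled=pd.DataFrame(scaled, index=scores.raw.index),
        scaling=constants,
    )


def write_scores(scores: ScoreMatrix, path: str | Path, metadata_path: str | Path | None = None) -> None:
    """Write scores.tsv (raw and scaled columns) plus a metadata JSON."""
    out = scores.raw.add_suffix("_raw")
    if scores.scaled is not None:
        out = out.join(scores.scaled.add_suffix("_scaled"))
    out.rename_axis("subject_id").to_csv(path, sep="\t", float_format="%.17g")
    if metadata_path is not None:
        meta = {
            "apoe_included": scores.apoe_included,
            "variant_sets": {k: list(v) for k, v in scores.variant_sets.items()},
            "scaling": scores.scaling,
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2))


def read_scores(path: str | Path, apoe_included: bool = True) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    raw = df[[c for c in df.columns if c.endswith("_raw")]].rename(
        columns=lambda c: c[: -len("_raw")]
    )
    scaled_cols = [c for c in df.columns if c.endswith("_scaled")]
    scaled = (
        df[scaled_cols].rename(columns=lambda c: c[: -len("_scaled")])
        if scaled_cols
        else None
    )
    return ScoreMatrix(
        df.index.astype(str).tolist(), raw, apoe_included, {}, scaled=scaled
    )
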