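"""Core containers for the pathway-PRS pipeline.

The pipeline works on four kinds of input: a curated table of
disease-associated variants with published effect sizes, a subjects x
variants matrix of effect-allele dosages, a phenotype/covariate table for
three cohorts (general population ``P``, Alzheimer's disease cases ``A``,
cognitively healthy centenarians ``C``), and a set of annotation lists
linking variants to candidate genes and genes to biological pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The five canonical AD pathways, in reporting order.
PATHWAYS: tuple[str, ...] = (
    "immune_response",
    "beta_amyloid",
    "endocytosis",
    "cholesterol_lipid",
    "angiogenesis",
)

#: Reserved category absorbing variant weight not attributable to any pathway.
UNMAPPED: str = "unmapped"

#: All score columns carried by a ScoreMatrix: total PRS, five pathways, unmapped.
PRS_COLUMN: str = "PRS"

COHORTS: tuple[str, ...] = ("P", "A", "C")
SEXES: tuple[str, ...] = ("male", "female", "unknown")


class PathPRSError(Exception):
    """Base class for all pipeline errors."""


class ParseError(PathPRSError):
    """Malformed or inconsistent input table."""


class AlleleMismatchError(PathPRSError):
    """VCF record alleles match neither orientation of the variant table."""


class MissingDataError(PathPRSError):
    """Required values absent (missing variants, empty cohorts, ...)."""


class AnnotationError(PathPRSError):
    """Invalid annotation source content."""


class ScoreError(PathPRSError):
    """Scoring or scaling failure (missing weight rows, constant columns)."""


class FitFailureError(PathPRSError):
    """Logistic fit did not converge or the data are (quasi-)separated."""


class SimulationError(PathPRSError):
    """Synthetic-cohort generation failure."""


VARIANT_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "maf",
    "apoe_flag",
    "locus_label",
)


@dataclass
class VariantTable:
    """Curated variant panel with published per-allele log odds ratios.

    One row per variant: identifier, GRCh37 position, effect/other allele,
    effect size ``beta`` (log OR from literature), minor allele frequency
    ``maf`` (possibly NaN until estimated from population dosages), a flag
    marking the two APOE-locus variants, and a human-readable locus label.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"variant table missing columns: {missing}")
        if df["variant_id"].duplicated().any():
            dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ParseError(f"duplicate variant_id: {dups}")
        df = df.copy()
        for col in ("effect_allele", "other_allele"):
            df[col] = df[col].astype(str).str.upper()
        bad = df["effect_allele"] == df["other_allele"]
        if bad.any():
            raise ParseError(
                f"effect_allele equals other_allele for {df.loc[bad, 'variant_id'].tolist()}"
            )
        beta = pd.to_numeric(df["beta"], errors="coerce")
        if beta.isna().any():
            rows = df.index[beta.isna()].tolist()
            raise ParseError(f"non-numeric or missing beta at rows {rows}")
        if not np.isfinite(beta).all():
            raise ParseError("beta must be finite")
        df["beta"] = beta.astype(float)
        df["maf"] = pd.to_numeric(df["maf"], errors="coerce").astype(float)
        known = df["maf"].dropna()
        if ((known <= 0) | (known > 0.5)).any():
            raise ParseError("maf must lie in (0, 0.5]; fold frequencies above 0.5")
        df["apoe_flag"] = df["apoe_flag"].astype(bool)
        self.table = df.reset_index(drop=True)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    @property
    def beta(self) -> pd.Series:
        return self.table.set_index("variant_id")["beta"]

    @property
    def maf(self) -> pd.Series:
        return self.table.set_index("variant_id")["maf"]

    @property
    def apoe_ids(self) -> list[str]:
        t = self.table
        return t.loc[t["apoe_flag"], "variant_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, variant_ids: Sequence[str]) -> "VariantTable":
        keep = self.table["variant_id"].isin(set(variant_ids))
        return VariantTable(self.table.loc[keep].reset_index(drop=True))

    def without_apoe(self) -> "VariantTable":
        """The panel with exactly the apoe_flag variants removed."""
        keep = ~self.table["apoe_flag"]
        return VariantTable(self.table.loc[keep].reset_index(drop=True))

    def with_maf(self, maf: Mapping[str, float]) -> "VariantTable":
        df = self.table.copy()
        df["maf"] = df["variant_id"].map(maf).astype(float)
        return VariantTable(df)


@dataclass
class DosageMatrix:
    """Subjects x variants effect-allele dosages in [0, 2] with a missing mask."""

    subject_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    missing: np.ndarray
    #: variants requested but absent from the source (reported, never silent)
    missing_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = len(self.subject_ids), len(self.variant_ids)
        if self.dosages.shape != (n, m) or self.missing.shape != (n, m):
            raise ParseError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{n} subjects x {m} variants"
            )
        observed = self.dosages[~self.missing]
        if observed.size and (np.nanmin(observed) < 0 or np.nanmax(observed) > 2):
            raise ParseError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        vals = self.dosages.copy()
        vals[self.missing] = np.nan
        return pd.DataFrame(vals, index=self.subject_ids, columns=self.variant_ids)

    def subset_subjects(self, subject_ids: Sequence[str]) -> "DosageMatrix":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [index[s] for s in subject_ids]
        return DosageMatrix(
            list(subject_ids),
            list(self.variant_ids),
            self.dosages[rows],
            self.missing[rows],
            self.missing_variants,
        )

    def subset_variants(self, variant_ids: Sequence[str]) -> "DosageMatrix":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        absent = [v for v in variant_ids if v not in index]
        if absent:
            raise MissingDataError(f"variants absent from dosage matrix: {absent}")
        cols = [index[v] for v in variant_ids]
        return DosageMatrix(
            list(self.subject_ids),
            list(variant_ids),
            self.dosages[:, cols],
            self.missing[:, cols],
            self.missing_variants,
        )


PHENOTYPE_COLUMNS = ("subject_id", "cohort", "sex", "age") + tuple(
    f"pc{i}" for i in range(1, 6)
)


@dataclass
class PhenotypeTable:
    """Per-subject cohort label, sex, age and principal components 1-5.

    ``age`` is age at inclusion for population subjects and centenarians and
    age at onset for AD cases. Sex ``unknown`` is excluded only from
    sex-stratified analyses.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"phenotype table missing columns: {missing}")
        if df["subject_id"].duplicated().any():
            raise ParseError("duplicate subject_id in phenotype table")
        df = df.copy()
        if df["cohort"].isna().any():
            raise ParseError("cohort labels may not be missing")
        bad = ~df["cohort"].isin(COHORTS)
        if bad.any():
            raise ParseError(
                f"unknown cohort labels: {sorted(df.loc[bad, 'cohort'].unique())}"
            )
        df["sex"] = df["sex"].fillna("unknown")
        bad = ~df["sex"].isin(SEXES)
        if bad.any():
            raise ParseError(f"unknown sex labels: {sorted(df.loc[bad, 'sex'].unique())}")
        pcs = df[[f"pc{i}" for i in range(1, 6)]].apply(pd.to_numeric, errors="coerce")
        if not np.isfinite(pcs.to_numpy()).all():
            raise ParseError("principal components must be finite")
        df[pcs.columns] = pcs
        self.table = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def cohort_subjects(self, cohort: str) -> list[str]:
        t = self.table
        return t.loc[t["cohort"] == cohort, "subject_id"].tolist()

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("subject_id")


@dataclass
class AnnotationSources:
    """Static annotation lists consumed by the weighting machinery.

    ``variant_gene_lists``: two named lists of (variant_id, gene) pairs,
    emulating the gene assignments of two independent GWAS annotation
    efforts. ``gene_pathway_lists``: four named lists of (gene, pathway)
    pairs (gene-set enrichment, ontology terms, functional clustering and a
    curated review). ``fixed_gene_map`` pins variants whose culprit gene is
    considered known to a single gene with weight 1.
    """

    variant_gene_lists: dict[str, pd.DataFrame]
    gene_pathway_lists: dict[str, pd.DataFrame]
    fixed_gene_map: dict[str, str] = field(default_factory=dict)
    pathway_universe: tuple[str, ...] = PATHWAYS

    def __post_init__(self) -> None:
        for name, df in self.variant_gene_lists.items():
            if not {"variant_id", "gene"} <= set(df.columns):
                raise AnnotationError(f"variant-gene list {name!r} needs variant_id, gene")
        for name, df in self.gene_pathway_lists.items():
            if not {"gene", "pathway"} <= set(df.columns):
                raise AnnotationError(f"gene-pathway list {name!r} needs gene, pathway")
            bad = ~df["pathway"].isin(self.pathway_universe)
            if bad.any():
                row = int(df.index[bad][0])
                raise AnnotationError(
                    f"gene-pathway list {name!r} row {row}: pathway "
                    f"{df.loc[df.index[bad][0], 'pathway']!r} outside the universe "
                    f"{list(self.pathway_universe)}"
                )
        self.fixed_gene_map = {
            str(k): str(v).upper() for k, v in self.fixed_gene_map.items()
        }


def score_columns(pathways: Iterable[str] = PATHWAYS) -> list[str]:
    """Column order of a ScoreMatrix: total PRS, each pathway, unmapped."""
    return [PRS_COLUMN, *pathways, UNMAPPED]
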