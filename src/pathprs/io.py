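"""Readers and writers for every external format the pipeline touches.

All tabular inputs are UTF-8 TSV with a header row and ``NA`` for missing
values. Genotype dosages come either from a VCF (``DS`` format field, or
hard ``GT`` calls converted to 0/1/2) or from a plain dosage TSV. Dosages
are always harmonised onto the effect allele of the variant table: when a
VCF record carries the effect allele as REF, the stored dosage is
``2 - DS``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    AlleleMismatchError,
    AnnotationSources,
    DosageMatrix,
    MissingDataError,
    ParseError,
    PhenotypeTable,
    VariantTable,
    PATHWAYS,
)

logger = logging.getLogger("pathprs")

_NA = ["NA", ""]


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def read_variant_table(path: str | Path) -> VariantTable:
    """Read variants.tsv into a validated :class:`VariantTable`."""
    df = _read_tsv(
        path,
        (
            "variant_id",
            "chrom",
            "pos",
            "effect_allele",
            "other_allele",
            "beta",
            "maf",
            "apoe_flag",
            "locus_label",
        ),
    )
    out = df.copy()
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any():
        raise ParseError(f"{path}: non-numeric pos at rows {df.index[pos.isna()].tolist()}")
    out["pos"] = pos.astype(int)
    beta = pd.to_numeric(df["beta"], errors="coerce")
    if beta.isna().any():
        rows = df.index[beta.isna()].tolist()
        raise ParseError(f"{path}: non-numeric beta at rows {rows}")
    out["beta"] = beta
    out["maf"] = pd.to_numeric(df["maf"], errors="coerce")
    out["apoe_flag"] = df["apoe_flag"].str.lower().map(
        {"true": True, "false": False, "1": True, "0": False}
    )
    if out["apoe_flag"].isna().any():
        rows = df.index[out["apoe_flag"].isna()].tolist()
        raise ParseError(f"{path}: apoe_flag must be true/false at rows {rows}")
    return VariantTable(out)


def write_variant_table(variants: VariantTable, path: str | Path) -> None:
    df = variants.table.copy()
    df["apoe_flag"] = df["apoe_flag"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = _read_tsv(path, ("subject_id", "cohort", "sex", "age") + tuple(f"pc{i}" for i in range(1, 6)))
    out = df.copy()
    out["age"] = pd.to_numeric(df["age"], errors="coerce")
    for i in range(1, 6):
        out[f"pc{i}"] = pd.to_numeric(df[f"pc{i}"], errors="coerce")
    return PhenotypeTable(out)


def write_phenotypes(phenotypes: PhenotypeTable, path: str | Path) -> None:
    phenotypes.table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_annotation_sources(
    variant_gene_path: str | Path,
    gene_pathway_path: str | Path,
    fixed_genes_path: str | Path | None = None,
    pathway_universe: tuple[str, ...] = PATHWAYS,
) -> AnnotationSources:
    """Read variant_gene.tsv, gene_pathway.tsv and optional fixed_genes.tsv.

    Both association tables carry a ``source`` column naming the annotation
    list each row belongs to; gene symbols are upper-cased (matching is
    exact, case-insensitive, no alias resolution).
    """
    vg = _read_tsv(variant_gene_path, ("source", "variant_id", "gene"))
    gp = _read_tsv(gene_pathway_path, ("source", "gene", "pathway"))
    vg["gene"] = vg["gene"].str.upper()
    gp["gene"] = gp["gene"].str.upper()
    vg_lists = {
        str(name): grp[["variant_id", "gene"]].reset_index(drop=True)
        for name, grp in vg.groupby("source", sort=True)
    }
    gp_lists = {
        str(name): grp[["gene", "pathway"]].reset_index(drop=True)
        for name, grp in gp.groupby("source", sort=True)
    }
    fixed: dict[str, str] = {}
    if fixed_genes_path is not None:
        fx = _read_tsv(fixed_genes_path, ("variant_id", "gene"))
        if fx["variant_id"].duplicated().any():
            raise ParseError(f"{fixed_genes_path}: duplicate variant_id")
        fixed = dict(zip(fx["variant_id"], fx["gene"].str.upper()))
    return AnnotationSources(vg_lists, gp_lists, fixed, pathway_universe)


def read_dosages_vcf(path: str | Path, variants: VariantTable) -> DosageMatrix:
    """Read effect-allele dosages for the panel variants from a VCF.

    Records are matched to the panel by ID, falling back to (chrom, pos).
    Dosage is taken from the per-sample ``DS`` field when present, else
    from hard ``GT`` calls (ALT-allele count); missing genotypes are
    masked. Panel variants absent from the VCF are recorded in
    ``missing_variants`` — never dropped silently.
    """
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    panel = variants.table.set_index("variant_id")
    by_pos = {
        (str(r.chrom), int(r.pos)): vid for vid, r in panel.iterrows()
    }
    wanted = set(panel.index)
    n = len(subjects)
    columns: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for record in vcf:
        vid = record.ID if record.ID in wanted else by_pos.get((str(record.CHROM), int(record.POS)))
        if vid is None or vid in columns:
            continue
        row = panel.loc[vid]
        if len(record.ALT) != 1:
            raise AlleleMismatchError(f"{vid}: multiallelic record not supported")
        ref, alt = record.REF.upper(), record.ALT[0].upper()
        if ref == row["other_allele"] and alt == row["effect_allele"]:
            flip = False
        elif ref == row["effect_allele"] and alt == row["other_allele"]:
            flip = True
        else:
            raise AlleleMismatchError(
                f"{vid}: VCF alleles {ref}/{alt} match neither orientation of "
                f"{row['effect_allele']}/{row['other_allele']}"
            )
        ds = record.format("DS")
        if ds is not None:
            vals = np.asarray(ds, dtype=float).reshape(n)
            mask = ~np.isfinite(vals) | (vals < 0)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(record.gt_types)
            vals = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
            mask = gt == 2
        if flip:
            vals = 2.0 - vals
        vals = np.where(mask, 0.0, vals)
        columns[vid] = (vals, mask)
    found = [v for v in panel.index if v in columns]
    absent = tuple(v for v in panel.index if v not in columns)
    if absent:
        logger.warning("variants absent from %s: %s", path, list(absent))
    dos = np.column_stack([columns[v][0] for v in found]) if found else np.empty((n, 0))
    msk = np.column_stack([columns[v][1] for v in found]) if found else np.empty((n, 0), bool)
    return DosageMatrix(subjects, found, dos, msk, missing_variants=absent)


def read_dosages_tsv(path: str | Path, variants: VariantTable | None = None) -> DosageMatrix:
    """Read a subject x variant dosage TSV (first column subject_id)."""
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    if df.columns[0] != "subject_id":
        raise ParseError(f"{path}: first column must be subject_id")
    df = df.set_index("subject_id")
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    mask = ~np.isfinite(vals)
    vals = np.where(mask, 0.0, vals)
    cols = [str(c) for c in df.columns]
    absent: tuple[str, ...] = ()
    if variants is not None:
        absent = tuple(v for v in variants.variant_ids if v not in cols)
        if absent:
            logger.warning("variants absent from %s: %s", path, list(absent))
    return DosageMatrix(df.index.astype(str).tolist(), cols, vals, mask, absent)


def write_dosages_tsv(dosages: DosageMatrix, path: str | Path) -> None:
    dosages.to_frame().rename_axis("subject_id").to_csv(
        path, sep="\t", na_rep="NA", float_format="%.17g"
    )


def fill_missing(dosages: DosageMatrix, variants: VariantTable) -> DosageMatrix:
    """Replace masked dosages by their expectation 2*MAF and clear the mask."""
    if not dosages.missing.any():
        return DosageMatrix(
            dosages.subject_ids, dosages.variant_ids,
            dosages.dosages.copy(), np.zeros_like(dosages.missing),
            dosages.missing_variants,
        )
    fully = dosages.missing.all(axis=0)
    if fully.any():
        bad = [dosages.variant_ids[i] for i in np.flatnonzero(fully)]
        raise MissingDataError(f"variants with all dosages missing: {bad}")
    maf = variants.maf
    absent = [v for v in dosages.variant_ids if v not in maf.index or not np.isfinite(maf[v])]
    cols_needing = {dosages.variant_ids[i] for i in np.flatnonzero(dosages.missing.any(axis=0))}
    absent = [v for v in absent if v in cols_needing]
    if absent:
        raise MissingDataError(f"no MAF available to fill missing dosages for {absent}")
    fill = np.array(
        [2.0 * maf.get(v, np.nan) for v in dosages.variant_ids], dtype=float
    )
    vals = dosages.dosages.copy()
    rows, cols = np.nonzero(dosages.missing)
    vals[rows, cols] = fill[cols]
    return DosageMatrix(
        dosages.subject_ids, dosages.variant_ids, vals,
        np.zeros_like(dosages.missing), dosages.missing_variants,
    )


def estimate_maf(
    dosages: DosageMatrix, phenotypes: PhenotypeTable, cohort: str = "P"
) -> pd.DataFrame:
    """Per-variant allele frequency in one cohort, folded to the minor allele.

    Frequency is mean(dosage)/2 over the cohort's subjects (masked entries
    ignored). Frequencies above 0.5 are folded to ``1 - f`` with the
    ``folded`` flag set; monomorphic variants are flagged ``degenerate``.
    Returns a frame indexed by variant_id with columns ``af`` (raw),
    ``maf`` (folded), ``folded``, ``degenerate``.
    """
    members = set(phenotypes.cohort_subjects(cohort))
    rows = [i for i, s in enumerate(dosages.subject_ids) if s in members]
    if not rows:
        raise MissingDataError(f"no subjects in cohort {cohort!r}")
    vals = np.ma.masked_array(dosages.dosages[rows], mask=dosages.missing[rows])
    af = np.asarray(vals.mean(axis=0) / 2.0)
    folded = af > 0.5
    maf = np.where(folded, 1.0 - af, af)
    return pd.DataFrame(
        {
            "af": af,
            "maf": maf,
            "folded": folded,
            "degenerate": (maf <= 0.0) | (maf >= 1.0),
        },
        index=pd.Index(dosages.variant_ids, name="variant_id"),
    )


def match_subjects(
    dosages: DosageMatrix, phenotypes: PhenotypeTable
) -> tuple[DosageMatrix, PhenotypeTable]:
    """Intersect dosage and phenotype subjects by exact ID, logging drops."""
    dos_ids = set(dosages.subject_ids)
    phe_ids = set(phenotypes.subject_ids)
    shared = [s for s in dosages.subject_ids if s in phe_ids]
    dropped = (len(dos_ids) - len(shared), len(phe_ids) - len(shared))
    if any(dropped):
        logger.warning(
            "dropped %d genotyped and %d phenotyped subjects without a match",
            *dropped,
        )
    if not shared:
        raise MissingDataError("no subjects shared between dosages and phenotypes")
    phe = phenotypes.table.set_index("subject_id").loc[shared].reset_index()
    return dosages.subset_subjects(shared), PhenotypeTable(phe)
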