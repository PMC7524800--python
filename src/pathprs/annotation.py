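"""Weighted variant-gene-pathway annotation.

A variant's involvement in each pathway is quantified in three steps:

1. *variant-gene* weights ``m_g^k``: across two independent annotation
   lists, count how often variant ``k`` is linked to gene ``g`` and divide
   by the variant's total number of (variant, gene) association instances,
   so the weights form a distribution over candidate genes. Variants whose
   culprit gene is considered known (fixed-gene overrides) get a single
   gene with weight 1.
2. *gene-pathway* weights ``w_p^g``: the same counting over four
   gene-pathway lists. Genes linked to none of the pathways are excluded
   (kept aside as ``unmapped_genes``).
3. *variant-pathway* weights ``M_p^k = sum_g m_g^k * w_p^g`` over mapped
   genes; variant-gene mass sitting on unmapped genes is routed to the
   reserved ``unmapped`` category so that every variant's weights sum to 1.

Duplicate pairs within one source list are de-duplicated before counting
(a source either supports an association or it does not); repeats across
sources do count — that is what the counting expresses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .datatypes import AnnotationSources, MissingDataError, PATHWAYS, UNMAPPED

logger = logging.getLogger("pathprs")

_SUM_TOL = 1e-12


@dataclass
class VariantGeneWeights:
    """Distribution over candidate genes per variant (``m_g^k``)."""

    weights: dict[str, dict[str, float]]
    #: variants with no gene association and no fixed override
    geneless: tuple[str, ...] = ()

    def genes(self) -> set[str]:
        return {g for w in self.weights.values() for g in w}


@dataclass
class GenePathwayWeights:
    """Distribution over pathways per mapped gene (``w_p^g``)."""

    weights: dict[str, dict[str, float]]
    unmapped_genes: frozenset[str] = frozenset()


@dataclass
class VariantPathwayWeights:
    """Per-variant distribution over the five pathways plus ``unmapped``."""

    weights: dict[str, dict[str, float]]
    pathways: tuple[str, ...] = PATHWAYS

    def __post_init__(self) -> None:
        cols = (*self.pathways, UNMAPPED)
        for vid, row in self.weights.items():
            full = {p: float(row.get(p, 0.0)) for p in cols}
            total = sum(full.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"weights for {vid} sum to {total}, expected 1")
            self.weights[vid] = full

    def to_frame(self) -> pd.DataFrame:
        cols = [*self.pathways, UNMAPPED]
        df = pd.DataFrame.from_dict(self.weights, orient="index")[cols]
        df.index.name = "variant_id"
        return df

    def complete(self, variant_ids: list[str]) -> "VariantPathwayWeights":
        """Add weight-1 ``unmapped`` rows for variants without a mapping."""
        out = dict(self.weights)
        for vid in variant_ids:
            if vid not in out:
                out[vid] = {UNMAPPED: 1.0}
        return VariantPathwayWeights(out, self.pathways)


def _count_weights(pairs_by_source: dict[str, pd.DataFrame], key: str, value: str):
    """Shared counting rule: de-dup within source, count across sources."""
    counted: list[pd.DataFrame] = []
    for name, df in pairs_by_source.items():
        if df.empty:
            continue
        counted.append(df[[key, value]].dropna().drop_duplicates())
    if not counted:
        return {}
    stacked = pd.concat(counted, ignore_index=True)
    weights: dict[str, dict[str, float]] = {}
    for k, grp in stacked.groupby(key, sort=True):
        counts = grp[value].value_counts()
        total = int(counts.sum())
        weights[str(k)] = {str(v): c / total for v, c in counts.items()}
    return weights


def build_variant_gene_weights(sources: AnnotationSources) -> VariantGeneWeights:
    """Count variant-gene associations across the two annotation lists."""
    if all(df.empty for df in sources.variant_gene_lists.values()):
        if not sources.fixed_gene_map:
            raise MissingDataError("all variant-gene lists are empty")
    lists = {
        name: df.assign(gene=df["gene"].str.upper())
        for name, df in sources.variant_gene_lists.items()
    }
    weights = _count_weights(lists, "variant_id", "gene")
    for vid, gene in sources.fixed_gene_map.items():
        weights[vid] = {gene: 1.0}  # culprit gene assumed known: 1:1
    listed = {str(v) for df in lists.values() for v in df["variant_id"].dropna()}
    geneless = tuple(sorted(listed - set(weights)))
    if geneless:
        logger.warning("variants with no gene association: %s", list(geneless))
    return VariantGeneWeights(weights, geneless)


def build_gene_pathway_weights(
    sources: AnnotationSources, genes: set[str] | None = None
) -> GenePathwayWeights:
    """Count gene-pathway associations across the four annotation lists.

    ``genes`` restricts the universe (typically the genes reached by the
    variant-gene mapping); genes in the universe with zero associations go
    to ``unmapped_genes``.
    """
    lists = {
        name: df.assign(gene=df["gene"].str.upper())
        for name, df in sources.gene_pathway_lists.items()
    }
    weights = _count_weights(lists, "gene", "pathway")
    if genes is None:
        genes = set(weights)
    genes = {g.upper() for g in genes}
    weights = {g: w for g, w in weights.items() if g in genes}
    unmapped = frozenset(genes - set(weights))
    return GenePathwayWeights(weights, unmapped)


def combine_mappings(
    vg: VariantGeneWeights, gp: GenePathwayWeights,
    pathways: tuple[str, ...] = PATHWAYS,
) -> VariantPathwayWeights:
    """Compose the two mappings: ``M_p^k = sum_g m_g^k * w_p^g``.

    Variant-gene mass on genes without any pathway association becomes the
    variant's ``unmapped`` weight, so each row remains a distribution.
    """
    out: dict[str, dict[str, float]] = {}
    for vid, gene_w in vg.weights.items():
        row = {p: 0.0 for p in pathways}
        row[UNMAPPED] = 0.0
        for gene, m in gene_w.items():
            pw = gp.weights.get(gene)
            if pw is None:
                row[UNMAPPED] += m
            else:
                for p, w in pw.items():
                    row[p] += m * w
        out[vid] = row
    return VariantPathwayWeights(out, pathways)


def mapping_summary(
    vpw: VariantPathwayWeights,
    vg: VariantGeneWeights | None = None,
    gp: GenePathwayWeights | None = None,
) -> dict:
    """Counts reported alongside a mapping.

    Per pathway, the number of variants with strictly positive weight; the
    number of mapped loci (variants reaching at least one named pathway);
    and, when the intermediate mappings are supplied, the number of
    variant-linked genes and of pathway-mapped genes.
    """
    per_pathway = {
        p: sum(1 for row in vpw.weights.values() if row.get(p, 0.0) > 0.0)
        for p in vpw.pathways
    }
    mapped_loci = sum(
        1
        for row in vpw.weights.values()
        if any(row.get(p, 0.0) > 0.0 for p in vpw.pathways)
    )
    unmapped_variants = sum(
        1 for row in vpw.weights.values() if row.get(UNMAPPED, 0.0) >= 1.0 - _SUM_TOL
    )
    summary = {
        "n_variants": len(vpw.weights),
        "variants_per_pathway": per_pathway,
        "n_mapped_loci": mapped_loci,
        "n_fully_unmapped_variants": unmapped_variants,
    }
    if vg is not None:
        summary["n_variant_linked_genes"] = len(vg.genes())
    if gp is not None:
        summary["n_pathway_mapped_genes"] = len(gp.weights)
        summary["n_unmapped_genes"] = len(gp.unmapped_genes)
    return summary


def build_variant_pathway_weights(
    sources: AnnotationSources,
) -> tuple[VariantPathwayWeights, dict]:
    """End-to-end convenience: sources -> combined weights + summary."""
    vg = build_variant_gene_weights(sources)
    gp = build_gene_pathway_weights(sources, vg.genes())
    vpw = combine_mappings(vg, gp, sources.pathway_universe)
    return vpw, mapping_summary(vpw, vg, gp)


def write_variant_pathway_weights(vpw: VariantPathwayWeights, path: str | Path) -> None:
    vpw.to_frame().to_csv(path, sep="\t", float_format="%.12g")


def read_variant_pathway_weights(path: str | Path) -> VariantPathwayWeights:
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    pathways = tuple(c for c in df.columns if c != UNMAPPED)
    return VariantPathwayWeights(
        {str(v): row.to_dict() for v, row in df.iterrows()}, pathways
    )
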