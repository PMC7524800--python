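"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study design end to end: a panel of 29 common
AD-associated variants (two large-effect APOE-locus variants plus 27
variants with |log OR| between 0.06 and 0.28), Hardy-Weinberg genotypes in
linkage equilibrium, a logistic disease model acting through the true PRS,
a centenarian (resilience) phenotype depleted of risk alleles through a
negative per-SD log-OR, and toy annotation tables whose recounting
reproduces a known variant-pathway mapping exactly.

Default cohort sizes (1654 population / 1895 case / 293 centenarian), age
distributions and generative per-SD log-ORs (risk 0.96, resilience -0.62)
match the regime of the cohorts the pipeline is designed for. Population
subjects are drawn conditional on non-case status (population controls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .annotation import VariantPathwayWeights
from .datatypes import (
    AnnotationSources,
    DosageMatrix,
    PhenotypeTable,
    SimulationError,
    VariantTable,
    PATHWAYS,
    UNMAPPED,
)

# ---------------------------------------------------------------------------
# Default variant panel: id, chrom, pos (GRCh37), effect allele, other
# allele, effect-allele frequency (== MAF, all kept <= 0.5), log OR, APOE
# flag, locus label. Effect sizes and frequencies emulate the published
# common-variant AD panel regime.
_PANEL = [
    ("rs6656401", "1", 207692049, "A", "G", 0.197, 0.16, False, "CR1"),
    ("rs6733839", "2", 127892810, "T", "C", 0.409, 0.20, False, "BIN1"),
    ("rs35349669", "2", 234068476, "T", "C", 0.488, 0.07, False, "INPP5D"),
    ("rs9271058", "6", 32575406, "A", "T", 0.280, 0.10, False, "HLA-DRB1"),
    ("rs9473117", "6", 47431284, "C", "A", 0.271, 0.09, False, "CD2AP"),
    ("rs12539172", "7", 100091795, "T", "C", 0.306, -0.09, False, "NYAP1"),
    ("rs1859788", "7", 99971834, "A", "G", 0.317, -0.10, False, "PILRA"),
    ("rs10808026", "7", 143110762, "A", "C", 0.198, -0.10, False, "EPHA1"),
    ("rs73223431", "8", 27219987, "T", "C", 0.365, 0.09, False, "PTK2B"),
    ("rs9331896", "8", 27467686, "C", "T", 0.379, -0.15, False, "CLU"),
    ("rs7920721", "10", 11720308, "G", "A", 0.389, 0.08, False, "ECHDC3"),
    ("rs3740688", "11", 47380340, "G", "T", 0.449, -0.09, False, "SPI1"),
    ("rs983392", "11", 59923508, "G", "A", 0.399, -0.11, False, "MS4A6A"),
    ("rs10792832", "11", 85867875, "A", "G", 0.358, -0.13, False, "PICALM"),
    ("rs11218343", "11", 121435587, "C", "T", 0.040, -0.21, False, "SORL1"),
    ("rs17125924", "14", 53391680, "G", "A", 0.090, 0.13, False, "FERMT2"),
    ("rs12881735", "14", 92932828, "C", "T", 0.216, -0.08, False, "SLC24A4"),
    ("rs593742", "15", 59045774, "G", "A", 0.301, -0.07, False, "ADAM10"),
    ("rs117618017", "15", 63569902, "T", "C", 0.132, 0.10, False, "APH1B"),
    ("rs59735493", "16", 31133100, "A", "G", 0.296, -0.07, False, "KAT8"),
    ("rs72824905", "16", 81942028, "G", "C", 0.013, -0.28, False, "PLCG2"),
    ("rs138190086", "17", 61538148, "A", "G", 0.020, 0.11, False, "ACE"),
    ("rs2732703", "17", 44353222, "G", "T", 0.200, 0.07, False, "KANSL1"),
    ("rs4147929", "19", 1063443, "A", "G", 0.190, 0.14, False, "ABCA7"),
    ("rs429358", "19", 45411941, "C", "T", 0.217, 1.20, True, "APOE"),
    ("rs7412", "19", 45412079, "T", "C", 0.078, -0.47, True, "APOE"),
    ("rs3865444", "19", 51727962, "A", "C", 0.307, -0.06, False, "CD33"),
    ("rs6024870", "20", 54997568, "A", "G", 0.089, -0.12, False, "CASS4"),
    ("rs2830500", "21", 28156856, "A", "C", 0.289, -0.07, False, "ADAMTS1"),
]

#: Variants whose culprit gene is treated as known (1:1 variant-gene link).
DEFAULT_FIXED_GENES = {
    "rs6656401": "CR1",
    "rs1859788": "PILRA",
    "rs72824905": "PLCG2",
    "rs4147929": "ABCA7",
    "rs429358": "APOE",
    "rs7412": "APOE",
}

#: Ground-truth variant-pathway mapping for the default panel. All weights
#: are small-denominator rationals so toy annotation tables can encode them
#: exactly by counting.
DEFAULT_TRUE_WEIGHTS: dict[str, dict[str, float]] = {
    "rs6656401": {"immune_response": 1.0},
    "rs6733839": {"endocytosis": 2 / 3, "beta_amyloid": 1 / 3},
    "rs35349669": {"immune_response": 1.0},
    "rs9271058": {"immune_response": 1.0},
    "rs9473117": {"endocytosis": 1 / 2, UNMAPPED: 1 / 2},
    "rs12539172": {UNMAPPED: 1.0},
    "rs1859788": {"immune_response": 1.0},
    "rs10808026": {"immune_response": 1 / 2, "angiogenesis": 1 / 2},
    "rs73223431": {"immune_response": 1 / 3, "endocytosis": 1 / 3, UNMAPPED: 1 / 3},
    "rs9331896": {"beta_amyloid": 1 / 2, "cholesterol_lipid": 1 / 4, "immune_response": 1 / 4},
    "rs7920721": {UNMAPPED: 1.0},
    "rs3740688": {"immune_response": 1.0},
    "rs983392": {"immune_response": 1.0},
    "rs10792832": {"endocytosis": 2 / 3, "beta_amyloid": 1 / 3},
    "rs11218343": {"endocytosis": 1 / 2, "beta_amyloid": 1 / 2},
    "rs17125924": {"angiogenesis": 1 / 2, UNMAPPED: 1 / 2},
    "rs12881735": {UNMAPPED: 1.0},
    "rs593742": {"beta_amyloid": 1.0},
    "rs117618017": {"beta_amyloid": 1.0},
    "rs59735493": {UNMAPPED: 1.0},
    "rs72824905": {"immune_response": 3 / 5, "endocytosis": 2 / 5},
    "rs138190086": {"beta_amyloid": 1 / 2, "angiogenesis": 1 / 2},
    "rs2732703": {UNMAPPED: 1.0},
    "rs4147929": {"cholesterol_lipid": 1 / 2, "beta_amyloid": 1 / 4, "immune_response": 1 / 4},
    "rs429358": {"cholesterol_lipid": 1 / 2, "beta_amyloid": 1 / 4, "immune_response": 1 / 8, "endocytosis": 1 / 8},
    "rs7412": {"cholesterol_lipid": 1 / 2, "beta_amyloid": 1 / 4, "immune_response": 1 / 8, "endocytosis": 1 / 8},
    "rs3865444": {"immune_response": 1.0},
    "rs6024870": {"endocytosis": 1 / 2, UNMAPPED: 1 / 2},
    "rs2830500": {"angiogenesis": 1.0},
}

#: maximum common denominator for encodable annotation weights
MAX_COUNTS = 12

_AGE_BY_COHORT = {"P": (62.7, 6.4), "A": (69.2, 9.9), "C": (101.4, 1.3)}


def default_variant_table() -> VariantTable:
    df = pd.DataFrame(
        _PANEL,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "maf", "beta", "apoe_flag", "locus_label",
        ],
    )
    return VariantTable(df)


def default_true_weights() -> VariantPathwayWeights:
    return VariantPathwayWeights(
        {v: dict(w) for v, w in DEFAULT_TRUE_WEIGHTS.items()}
    )


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic three-cohort study."""

    n_population: int = 1654
    n_case: int = 1895
    n_centenarian: int = 293
    #: per-SD log odds ratio of case status on the true PRS
    b_risk: float = 0.96
    #: per-SD log odds ratio of centenarian status (negative: depletion)
    b_resilience: float = -0.62
    #: baseline probabilities at PRS = population mean (sampling efficiency
    #: knobs; they shift intercepts only, never the slopes)
    case_prevalence: float = 0.25
    centenarian_prevalence: float = 0.15
    n_pcs: int = 5
    seed: int = 0
    variants: VariantTable = field(default_factory=default_variant_table)
    fixed_genes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FIXED_GENES))

    def __post_init__(self) -> None:
        if min(self.n_population, self.n_case, self.n_centenarian) < 0:
            raise SimulationError("cohort sizes must be non-negative")
        if self.seed is None:
            raise SimulationError("a seed is mandatory")
        maf = self.variants.maf
        if ((maf <= 0) | (maf > 0.5)).any():
            raise SimulationError("variant MAFs must lie in (0, 0.5]")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("variants", "fixed_genes")
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update(overrides)
        return cls(**payload)


@dataclass
class SimulatedCohort:
    """Dosages, phenotypes and the generative truth of one simulation."""

    dosages: DosageMatrix
    phenotypes: PhenotypeTable
    truth: dict


def simulate_genotypes(config: SimulationConfig, n: int | None = None) -> DosageMatrix:
    """Hardy-Weinberg genotypes in linkage equilibrium: binomial(2, MAF)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_population if n is None else n
    maf = config.variants.maf.to_numpy()
    dosages = rng.binomial(2, maf, size=(n, maf.size)).astype(float)
    ids = [f"S{i:06d}" for i in range(n)]
    return DosageMatrix(
        ids, config.variants.variant_ids, dosages, np.zeros_like(dosages, bool)
    )


def _prs_moments(variants: VariantTable) -> tuple[float, float]:
    maf = variants.maf.to_numpy()
    beta = variants.beta.to_numpy()
    mean = float(np.sum(2 * maf * beta))
    var = float(np.sum(beta**2 * 2 * maf * (1 - maf)))
    return mean, math.sqrt(var)


def simulate_cohorts(
    config: SimulationConfig, max_batches: int = 1000
) -> SimulatedCohort:
    """Assemble the three cohorts by rejection sampling.

    Subjects are drawn from the population genotype model; case status is
    Bernoulli with logit ``logit(case_prevalence) + b_risk * z(PRS)`` and
    centenarian status with logit ``logit(centenarian_prevalence) +
    b_resilience * z(PRS)``, where ``z`` standardises the raw PRS by its
    analytic population moments. Each draw fills at most one quota:
    centenarians (status 1 under the resilience model), then cases
    (status 1), then population subjects (status 0 under the risk model).
    """
    rng = np.random.default_rng(config.seed)
    variants = config.variants
    maf = variants.maf.to_numpy()
    beta = variants.beta.to_numpy()
    mu, sigma = _prs_moments(variants)
    a_case = logit(config.case_prevalence)
    a_cent = logit(config.centenarian_prevalence)

    quotas = {"C": config.n_centenarian, "A": config.n_case, "P": config.n_population}
    kept: dict[str, list[np.ndarray]] = {c: [] for c in quotas}
    counts = {c: 0 for c in quotas}
    batch = max(2048, 2 * max(quotas.values()))
    for _ in range(max_batches):
        if all(counts[c] >= quotas[c] for c in quotas):
            break
        G = rng.binomial(2, maf, size=(batch, maf.size)).astype(float)
        z = (G @ beta - mu) / sigma
        is_case = rng.random(batch) < expit(a_case + config.b_risk * z)
        is_cent = rng.random(batch) < expit(a_cent + config.b_resilience * z)
        assigned = np.zeros(batch, bool)
        for cohort, mask in (("C", is_cent), ("A", is_case), ("P", ~is_case)):
            need = quotas[cohort] - counts[cohort]
            if need <= 0:
                continue
            take = np.flatnonzero(mask & ~assigned)[:need]
            if take.size:
                kept[cohort].append(G[take])
                counts[cohort] += take.size
                assigned[take] = True
    unfilled = {c: quotas[c] - counts[c] for c in quotas if counts[c] < quotas[c]}
    if unfilled:
        raise SimulationError(
            f"rejection sampling exhausted {max_batches} batches with quotas "
            f"unfilled: {unfilled}; increase max_batches or the baseline "
            "prevalences"
        )

    blocks, subject_ids, cohorts = [], [], []
    for cohort in ("P", "A", "C"):
        if quotas[cohort] == 0:
            continue
        block = np.vstack(kept[cohort])[: quotas[cohort]]
        blocks.append(block)
        subject_ids += [f"{cohort}{i:05d}" for i in range(quotas[cohort])]
        cohorts += [cohort] * quotas[cohort]
    G = np.vstack(blocks)
    n = G.shape[0]
    dosages = DosageMatrix(
        subject_ids, variants.variant_ids, G, np.zeros_like(G, bool)
    )
    ages = np.array(
        [rng.normal(*_AGE_BY_COHORT[c]) for c in cohorts]
    )
    phe = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "cohort": cohorts,
            "sex": rng.choice(["male", "female"], size=n),
            "age": np.round(ages, 1),
        }
    )
    pcs = rng.normal(size=(n, 5))
    if config.n_pcs < 5:
        pcs[:, config.n_pcs:] = 0.0
    for i in range(5):
        phe[f"pc{i + 1}"] = pcs[:, i]
    truth = {
        "b_risk": config.b_risk,
        "b_resilience": config.b_resilience,
        "prs_mean": mu,
        "prs_sd": sigma,
        "seed": config.seed,
    }
    return SimulatedCohort(dosages, PhenotypeTable(phe), truth)


def _as_fraction(weight: float) -> Fraction:
    frac = Fraction(weight).limit_denominator(MAX_COUNTS)
    if abs(float(frac) - weight) > 1e-9:
        raise SimulationError(
            f"weight {weight} is not representable with <= {MAX_COUNTS} counts"
        )
    return frac


def simulate_annotations(
    config: SimulationConfig, true_weights: VariantPathwayWeights
) -> AnnotationSources:
    """Emit annotation lists whose recounting reproduces ``true_weights``.

    For an ordinary variant with common-denominator-``D`` weights, ``D``
    synthetic genes each receive one variant-gene pair (weight ``1/D``)
    and one gene-pathway pair in the pathway their share dictates (none
    for the unmapped share). Variants in the fixed-gene map get a single
    gene whose pathway counts are spread across the gene-pathway source
    lists (so per-pathway counts above the number of lists are not
    encodable and raise an error).
    """
    vg_rows: list[tuple[str, str, str]] = []
    gp_rows: list[tuple[str, str, str]] = []
    gp_sources = ["magma", "go", "david", "review"]
    fixed = {
        v: g for v, g in config.fixed_genes.items() if v in true_weights.weights
    }
    for vid, row in true_weights.weights.items():
        shares = {p: w for p, w in row.items() if w > 0.0}
        fracs = {p: _as_fraction(w) for p, w in shares.items()}
        if abs(sum(float(f) for f in fracs.values()) - 1.0) > 1e-9:
            raise SimulationError(f"weights for {vid} do not sum to 1")
        denom = math.lcm(*(f.denominator for f in fracs.values()))
        if denom > MAX_COUNTS:
            raise SimulationError(
                f"weights for {vid} need {denom} counts (> {MAX_COUNTS})"
            )
        if vid in fixed:
            gene = fixed[vid]
            unmapped_share = float(fracs.get(UNMAPPED, 0))
            if 0.0 < unmapped_share < 1.0:
                raise SimulationError(
                    f"{vid}: a fixed-gene variant cannot carry partial unmapped weight"
                )
            vg_rows.append(("study1", vid, gene))
            for p, f in fracs.items():
                if p == UNMAPPED:
                    continue
                count = f.numerator * denom // f.denominator
                if count > len(gp_sources):
                    raise SimulationError(
                        f"{vid}: pathway count {count} for {p} exceeds the "
                        f"{len(gp_sources)} gene-pathway sources"
                    )
                for src in gp_sources[:count]:
                    gp_rows.append((src, gene, p))
        else:
            g = 0
            for p, f in fracs.items():
                count = f.numerator * denom // f.denominator
                for _ in range(count):
                    gene = f"G_{vid}_{g}"
                    g += 1
                    vg_rows.append(("study1", vid, gene))
                    if p != UNMAPPED:
                        gp_rows.append(("magma", gene, p))
    vg = pd.DataFrame(vg_rows, columns=["source", "variant_id", "gene"])
    gp = pd.DataFrame(gp_rows, columns=["source", "gene", "pathway"])
    vg_lists = {
        name: grp[["variant_id", "gene"]].reset_index(drop=True)
        for name, grp in vg.groupby("source")
    }
    vg_lists.setdefault("study2", pd.DataFrame(columns=["variant_id", "gene"]))
    gp_lists = {
        name: grp[["gene", "pathway"]].reset_index(drop=True)
        for name, grp in gp.groupby("source")
    }
    for name in gp_sources:
        gp_lists.setdefault(name, pd.DataFrame(columns=["gene", "pathway"]))
    return AnnotationSources(vg_lists, gp_lists, fixed, true_weights.pathways)


def write_vcf(dosages: DosageMatrix, variants: VariantTable, path: str | Path) -> None:
    """Write dosages as a plain-text VCF with a per-sample DS field."""
    panel = variants.table.set_index("variant_id")
    order = sorted(
        dosages.variant_ids,
        key=lambda v: (str(panel.loc[v, "chrom"]).zfill(2), int(panel.loc[v, "pos"])),
    )
    idx = {v: i for i, v in enumerate(dosages.variant_ids)}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(dosages.subject_ids),
    ]
    for vid in order:
        row = panel.loc[vid]
        col = dosages.dosages[:, idx[vid]]
        mask = dosages.missing[:, idx[vid]]
        vals = "\t".join(
            "." if m else f"{v:g}" for v, m in zip(col, mask)
        )
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['other_allele']}\t"
            f"{row['effect_allele']}\t.\tPASS\t.\tDS\t{vals}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotation_sources(
    sources: AnnotationSources,
    variant_gene_path: str | Path,
    gene_pathway_path: str | Path,
    fixed_genes_path: str | Path | None = None,
) -> None:
    vg = pd.concat(
        [df.assign(source=name) for name, df in sources.variant_gene_lists.items()],
        ignore_index=True,
    )[["source", "variant_id", "gene"]]
    vg.to_csv(variant_gene_path, sep="\t", index=False)
    gp = pd.concat(
        [df.assign(source=name) for name, df in sources.gene_pathway_lists.items()],
        ignore_index=True,
    )[["source", "gene", "pathway"]]
    gp.to_csv(gene_pathway_path, sep="\t", index=False)
    if fixed_genes_path is not None:
        pd.DataFrame(
            sorted(sources.fixed_gene_map.items()), columns=["variant_id", "gene"]
        ).to_csv(fixed_genes_path, sep="\t", index=False)
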