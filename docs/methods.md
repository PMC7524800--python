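# Methods

## Model and procedure

`pathprs` treats polygenic risk of Alzheimer's disease as an additive
score over a curated panel of common variants and partitions that score
across five biological pathways (immune response, β-amyloid metabolism,
endocytosis, cholesterol/lipid dysfunction, angiogenesis) plus a reserved
*unmapped* category.

**Scores.** The total score of subject *s* is `PRS^s = Σ_k dos_k^s β_k`,
where `dos_k^s ∈ [0,2]` is the (possibly imputed) effect-allele dosage
and `β_k` the published per-allele log odds ratio. The pathway score
multiplies each term by the variant-pathway weight:
`pPRS_p^s = Σ_k dos_k^s β_k M_p^k`.

**Variant-pathway weights.** `M_p^k = Σ_g m_g^k w_p^g`, composed from

- *variant-gene* weights `m_g^k`: across two annotation lists, each
  de-duplicated within itself, count the (variant, gene) association
  instances and divide by the variant's total instance count. Dividing by
  instances (rather than by the number of distinct genes) makes the
  weights a probability distribution, which the variance decomposition
  requires. Variants whose culprit gene is treated as known are pinned to
  that single gene with weight 1.
- *gene-pathway* weights `w_p^g`: the same counting over four lists.
  Genes with no pathway association are excluded from the mapping and the
  variant-gene mass they carry is routed to *unmapped* instead of being
  renormalised over the mapped pathways — this keeps `Σ_p M_p^k = 1`
  without inflating mapped-pathway weights. Gene symbols match exactly
  and case-insensitively; alias resolution is out of scope.

**Association.** Each z-scaled score is the sole genetic predictor in a
maximum-likelihood logistic regression of status — AD cases vs population
(`A_vs_P`) and cognitively healthy centenarians vs population (`C_vs_P`)
— adjusted for principal components 1–5. Scaling constants (mean and
sample SD, n−1) are computed once over the pooled three-cohort sample and
reused for both contrasts, so coefficients read as log OR per pooled SD.
Sex enters by stratification only, never as a covariate, and age is not
adjusted for. Inference is Wald (SE, two-sided p, `exp(β̂ ± 1.96·se)`
CIs); no profile likelihood and no multiple-testing correction — raw
p-values carry threshold annotations at 5×10⁻², 5×10⁻⁴, 5×10⁻⁶.
Non-convergence or (quasi-)separation is a hard error rather than a
fallback: with a curated-panel score and cohorts in the thousands,
separation signals a data problem. AUC is the rank-based (Mann-Whitney)
statistic with ties counted half.

**Change in effect size.** Per score and APOE mode, the ratio
`|log OR_CvsP| / |log OR_AvsP|`; below 1 means a larger effect on risk
than on resilience. The 95% CI comes from parametric Monte-Carlo
(default 10,000 draws, minimum 1,000): the two log-ORs are drawn
independently from `N(β̂, se)` — the contrasts share only the population
cohort; that dependence is ignored and declared. The ratio uses absolute
values with an explicit sign-concordance flag, since the interesting
pattern is effects in opposite directions. Draws in which the risk
coefficient crosses zero are kept (the absolute ratio stays defined) and
their fraction is reported as a stability diagnostic. The with- vs
without-APOE ratios are compared by Welch's t on the two draw samples;
because this p-value scales with the draw count, the count is always
reported alongside it.

**Variance decomposition.** Treating variants as independent (the panel
is built from distinct loci; only the two APOE-locus variants violate
this), each pathway's percentage of polygenic risk variance is

    P^p = 100 · Σ_k M_p^k β_k² MAF_k(1−MAF_k) / Σ_k β_k² MAF_k(1−MAF_k)

with the Bernoulli variance term as written; the diploid constant
2·MAF(1−MAF) cancels in the ratio, and this invariance is tested
explicitly. Variants without a mapping row enter with `M_unmapped = 1`,
so the shares sum to exactly 100%. MAFs default to the population-cohort
estimate (mean dosage / 2, folded to ≤ 0.5 with a recorded flag; folding
never changes MAF(1−MAF)); reference MAFs can be supplied instead.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `exclude_apoe` | both modes run | drop the two APOE-flagged variants; scores are recomputed and rescaled from scratch, since scaling is nonlinear in the variant set |
| `n_draws` | 10,000 (min 1,000) | Monte-Carlo draws for ratio CIs |
| scaling population | pooled P+A+C | cohort set defining score SD units |
| MAF source | population cohort | frequency used in the variance decomposition |
| significance thresholds | 5×10⁻², 5×10⁻⁴, 5×10⁻⁶ | star annotations on association rows |

Missing dosages are filled with their expectation `2·MAF` (the data the
design targets are fully imputed, so missingness is incidental); this
preserves the cohort mean without injecting ad-hoc zeros. Subject
matching between genotypes and phenotypes is by exact string ID; drops
are logged, never silent. Coordinates are 1-based GRCh37 throughout.

## The synthetic generator

`pathprs.simulate` encodes the study conditions as defaults: a 29-variant
panel (two APOE-locus variants at log-OR 1.20 and −0.47; 27 variants with
|log OR| 0.06–0.28 and MAF 0.013–0.49), cohort sizes 1654/1895/293, age
distributions 62.7±6.4 (population), 69.2±9.9 (cases, age at onset),
101.4±1.3 (centenarians), and generative per-SD log-ORs `b_risk = 0.96`
and `b_resilience = −0.62`, matching the full-panel odds-ratio regime the
pipeline targets (≈2.6 for risk, ≈0.54 for resilience).

Genotypes are binomial(2, MAF) — Hardy-Weinberg, linkage equilibrium.
This ignores the real correlation between the two APOE variants and all
LD structure. Case and centenarian status are Bernoulli with logits
`logit(prevalence) + b·z(PRS)`, where `z` standardises the raw PRS by its
analytic population moments; cohorts are filled by rejection sampling
(centenarians first, then cases, then non-case population subjects), and
the baseline prevalences shift only intercepts, never slopes. Principal
components are standard-normal noise independent of status — real PCs
correlate with both genotype and cohort, so covariate adjustment does
real work only on real data. Ages and sex are decorative.

Two consequences worth knowing when reading test output:

- In a case-control sample drawn this way, the `A_vs_P` logistic
  coefficient on the *truth-standardised* score equals `b_risk` exactly
  (retrospective sampling leaves the slope invariant). The parameter-
  recovery checks therefore standardise by the generative moments.
- The full pipeline instead scales by the pooled-sample SD and uses
  population subjects not screened for centenarian status, so the
  `C_vs_P` estimate is attenuated relative to `b_resilience`. The
  pipeline's estimates are reported as what they are — contrasts under
  the study's sampling design — not as recoveries of the generative
  coefficient.

The annotation generator inverts the counting rules: it emits variant-gene
and gene-pathway lists whose recount reproduces a target mapping exactly,
provided every weight is a rational with common denominator ≤ 12 (and,
for fixed-gene variants, per-pathway counts no larger than the number of
gene-pathway sources). This is the round-trip oracle for the mapping
machinery.

Passing tests on synthetic data demonstrate the estimators' correctness
under the stated model; they do not validate imputation quality, LD
handling, population stratification control or annotation accuracy on
real cohorts.

## Numerical choices and degenerate inputs

- Weight rows and contribution tables must sum to 1 (resp. 100%) within
  1e-9; contributions are renormalised after summation to absorb float
  accumulation, and reports round to 1 decimal while machine output keeps
  full precision.
- Zero-variance score columns are an error by default; the pipeline drops
  them with a logged warning (an all-mapped panel yields a constant-zero
  unmapped column).
- Monomorphic variants contribute zero variance to the decomposition
  (warning, not error); a missing MAF is an error.
- A risk log-OR of exactly 0 makes the effect ratio undefined (error).
- VCF dosages are harmonised onto the panel's effect allele (`2 − DS`
  when the effect allele is REF); alleles matching neither orientation
  are a hard error, and panel variants absent from the VCF are reported,
  never dropped silently. The `DS` field is single-precision, so
  orientation round-trips agree to ~1e-7, not machine epsilon.
- Problem sizes used by the test suite and the reproduction script —
  200 replicates at n = 1000/1000 for parameter recovery, 1000 random
  instances for additivity, 100 annotation sets for the counting oracle,
  10,000 draws for ratio CIs — were chosen to make Monte-Carlo error
  comfortably smaller than the tolerances they check.

## Known limitations

- Curated-panel scores only: no genome-wide PRS, no LD clumping or
  thresholding, no rare-variant burden.
- Variance decomposition assumes independent variants and reports
  observed-scale shares; no liability-scale conversion.
- The two ratio draw samples are treated as independent in the Welch
  test, and the shared population cohort induces a (ignored) correlation
  between the risk and resilience estimates.
- Annotation inputs are static tables; the package does not query
  ontology or clustering services, and publishes no opinion on which
  annotation release to use.
- Upstream genotype QC, imputation, ancestry and relatedness filtering
  are out of scope and assumed done.
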