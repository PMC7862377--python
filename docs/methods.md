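# Methods

## Scope

`partherit` implements a partitioned-heritability workflow for a
quantitative trait and an a-priori gene set: QC → three-way SNP
partition (coding / buffer / rest) → per-partition GRMs → multi-component
AI-REML → enrichment with power-calibrated subsets and fixed-effects
meta-analysis → mixed-model association with gene-level aggregation and
gene-set overlap statistics → partitioned summary-based BLUP polygenic
scores validated in an independent cohort. A synthetic-data module
generates every input the pipeline consumes, so all claims about the
machinery are tested against known truth.

## Synthetic cohorts

**Genotypes.** Diploid dosages arise from a latent-Gaussian threshold
model: per haplotype, a standard-normal Markov chain runs along each LD
block and an allele is called where the latent variable exceeds the
upper-p quantile. The chain's step correlation is calibrated through the
tetrachoric relation so that the *genotype* correlation of adjacent SNPs
matches `within_block_corr` (solved by bisection on the bivariate-normal
orthant probability, cached on rounded frequencies). Allele frequency is
drawn once per block — strong LD between markers of very different
frequency is impossible (the Fréchet bound), as in real high-LD blocks.
Blocks are independent; chromosomes are independent; SNPs sit at fixed
spacing (default 2 kb). A separate `frequency_seed` lets several cohorts
(discovery, validation, LD reference) share a frequency spectrum while
drawing independent genotypes.

**Genes.** Fixed-length intervals placed without overlap in per-
chromosome slots; a configured subset is flagged as the a-priori gene
set. Placement failure (genome too small) is a configuration error, not
a silent retry.

**Phenotype.** y = Σ_k g_k + covariates + e. Within each partition a
configurable fraction of SNPs (default 10%) receives Gaussian effects on
standardized genotypes. With `exact_rescale` (default) each g_k and the
noise are rescaled so realized in-sample variances equal the h² targets
exactly — parameter-recovery tests then have known truth; switched off,
targets hold in expectation only. Default targets (0.5% / 3% / 5%, total
8.5%) mirror the magnitude reported for human tobacco consumption
(total h² of roughly 8–10%, concentrated partly in and around the gene
set). Covariates are sex (Bernoulli ½), age ~ N(58, 8) (years), centred
age², and a site code, with small linear effects. An `architecture`
argument replays another cohort's causal SNPs and effect sizes, which is
how a shared biology across cohorts is modelled in transfer studies.

**What the generator does not emulate:** realistic human MAF and LD
spectra, imputation dosages, relatedness structure, selection, or
assortative mating. Passing tests show the *machinery* is correct and
calibrated under a controlled architecture, not that any particular real
trait behaves this way.

## QC

Per-sample call rate (≥ 0.99) is applied first; SNP statistics are then
recomputed and SNPs are dropped for MAF (> 0.01 required), Hardy–
Weinberg exact p (> 10⁻⁴), and missingness (< 0.10), attributing each
removal to the first failed criterion in that order. The HWE test is the
exact conditional test (no mid-p), computed in log space and verified
against a rational-arithmetic enumeration. The "genotyping rate" filter
is read as per-sample call rate and the "missing genotype rate" as
per-SNP missingness (the PLINK `--mind`/`--geno` split); post-QC,
missing dosages are mean-imputed everywhere downstream.

## Partitioning

Only gene-set genes define regions; SNPs inside non-gene-set genes are
"rest". Coding takes precedence over buffer; overlapping gene-set
intervals are merged before labelling; flanks are clipped at position 1
and never cross chromosomes. Coordinates are 1-based inclusive. The
implementation (merged intervals + binary search) is tested against a
brute-force per-SNP scan at every standard buffer width
(0/5/10/25/35/50 kb).

## Relatedness

GRMs use sample allele frequencies, mean-imputation and a fixed divisor
m (not per-pair non-missing counts); identical to the per-pair
convention when missingness is zero, which holds post-QC for the
synthetic data. Note that centring at sample frequencies makes each GRM
row sum to ≈ 0, so the off-diagonal mean is −1/(n−1), not 0. Greedy
relatedness pruning removes, from the worst offending pair, the member
with more over-cutoff partners (ties: later sample); the default cutoff
0.05 operationalises "no closer than second cousins". PCs come from the
SVD of the standardized matrix without LD pruning — adequate for
synthetic panels, flagged for real-data use.

## AI-REML

V = Σ σ²_k A_k + σ²_e I. One EM step for stability, then AI updates
δ = AI⁻¹·score with step-halving whenever the REML log-likelihood would
decrease, so the accepted path is monotone. When a component is clamped
at the floor the joint AI direction can point downhill for the remaining
free components; if no scaled AI step improves the likelihood, the
iteration falls back to an EM update, which is always an ascent
direction, before declaring convergence. Components are constrained
at a floor of 10⁻⁶·var(y); convergence is |Δlogℓ| < 10⁻⁴ with at most
100 iterations (non-convergence is flagged, never silent). A singular AI
matrix (condition number > 10¹²) raises a non-identifiability error —
the canonical case is a GRM proportional to the identity, confounded
with the residual. Sampling covariance is the inverse AI at convergence;
h² shares carry delta-method SEs. Fixed covariates enter through the
projection P (exact REML), not by pre-residualising.

Two finite-sample properties matter for interpretation and are covered
by tests rather than hidden: (i) *boundary bias* — constrained REML is
positively biased for components whose truth lies within ~2 SE of zero
(the estimator cannot go negative), so unbiasedness is asserted only for
well-separated truths; (ii) *LD leakage* — when LD blocks span partition
boundaries, variance attribution smears between adjacent partitions;
the partition estimates remain covered by their (honest) standard errors
but are not unbiased for the generating targets.

The boundary LRT uses the ½χ²₀ + ½χ²₁ mixture. Its null calibration is
itself size-dependent at desk scale (slightly anticonservative for very
small n, conservative for large n with weak GRM structure); the
calibration study in the acceptance suite runs at n = 200, m = 600,
where the asymptotic reference applies.

## Enrichment, power, subsets, meta-analysis

expected h²_k = (m_k/M)·h²_total; enrichment = observed / expected;
significance by CI exclusion (|obs − exp| > 1.96·SE(obs)). The
alternative reading "enrichment statistic > 1.96" is exposed as
`rule="z"` but is not the default: an enrichment is a ratio and 1.96 is
a z-threshold, and the two disagree for strongly enriched small
components. h²_total for a model is the sum of that model's fitted
genetic shares (delta-method SE over the component covariance). Power
uses var(ĥ²) = 2/(n²·v) with a 1-df noncentral χ²; quartile-balanced
subsets are built by round-robin allocation within phenotype quartiles
(rotating the starting subset so compositions differ by at most one
sample per quartile). Fixed-effects inverse-variance pooling throughout;
no random-effects model is offered.

## Association and overlap

MLMA-LOCO re-estimates the two variance components once per left-out
chromosome and tests each SNP by GLS with covariates projected out; a
single-chromosome panel falls back to a non-LOCO mixed model with a
warning. The gene statistic is deliberately simple — Bonferroni min-p
over a symmetric 10 kb gene window — and is labelled a stand-in for
dedicated gene-based methods; BH-FDR is applied across scored genes.
Overlap statistics: Jaccard similarity; Fisher's exact test on a homolog
background reporting the *sample* odds ratio (a·d)/(b·c) as the headline
(with the conditional-MLE OR and exact CI alongside); and a permutation
test comparing the gene set's mean −log₁₀ gene p against random
same-size draws, with the add-one empirical p. Between-group signal
comparisons (e.g. genes from different model organisms) use a two-sided
rank-sum test on −log₁₀ gene p with BH correction across pairs — a
package choice where no canonical test exists.

## SBLUP polygenic scores

Reference LD is the empirical correlation matrix per chromosome with
entries beyond `ld_window_kb` (default 1000 kb) zeroed and ridge 0.01 at
the solve; λ = m_total(1/h²_snp − 1) uses the total SNP count and total
GWAS h², applied identically to all partitions. GWAS effects are moved
to the standardized scale via β·√(2p(1−p)) before solving. Scores are
sums of adjusted effects over standardized dosages; partition scores are
additive by construction (coding + buffer + rest = all). Validation
association is OLS with an intercept and six ancestry PCs, reporting the
score coefficient and incremental R² over the covariate-only model.

## Desk-scale study sizes

The acceptance studies run at sizes chosen to make each claim decisive
on a single CPU; they are the package's study conditions, stated here
once:

- parameter recovery: 100 seeds of n = 800, m = 6,000, truths
  (0.01, 0.03, 0.05) with exact rescaling; coverage of ±2 reported SEs.
- buffer-architecture detection: 20 runs of n = 3,600 (two quartile-
  balanced subsets), m = 2,000 with ~2% buffer SNPs (eight point genes
  with 5 kb flanks), all partition SNPs causal, LD blocks of 5 SNPs at
  r = 0.3 so blocks do not straddle partition boundaries.
- LRT null calibration: 200 replicates at n = 200, m = 600.
- LOCO null scan: n = 500, m = 2,000 over 4 chromosomes.
- SBLUP transfer: 20 replicates; discovery n = 600, validation n = 500,
  reference n = 500, m = 1,500, h²_coding = 0.20 on ~10% coding SNPs vs
  h²_rest = 0.05, shared frequency spectrum and replayed architecture.

## Known limitations

No liability-scale transform (the target trait is treated as
quantitative); no per-pair missingness handling in GRMs; no
random-effects meta-analysis; the gene statistic is not a full
gene-based association model; PCs are LD-unaware; the generator's
exchangeable samples carry no population or family structure, so the
covariate and PC corrections are exercised only lightly.
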