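# partherit

Partitioned SNP-heritability analysis with an a-priori gene set:
GREML variance components, heritability enrichment, gene-set overlap
statistics, and summary-based BLUP polygenic scores — with a synthetic
cohort generator so the whole pipeline is testable end to end.

## Who this is for

Statistical geneticists asking whether a set of genes chosen *before*
seeing human data — for example, human homologs of genes implicated by
model-organism experiments — concentrates the heritability of a
quantitative trait. The package implements the full chain of that
analysis: marker QC, exclusive SNP partitioning around the gene set,
per-partition genomic relatedness, multi-component restricted maximum
likelihood, enrichment with subset meta-analysis, mixed-model
association with gene-level aggregation and overlap tests, and
partitioned polygenic prediction in an independent cohort.

## The model

With disjoint SNP partitions k = 1..K (coding / buffer / rest), the
phenotype is modelled as

    y ~ N(Xβ, Σ_k σ²_k A_k + σ²_e I),

where A_k is the genomic relatedness matrix over partition k,

    A_k[i,j] = (1/m_k) Σ_{s∈k} (x_is − 2p_s)(x_js − 2p_s) / (2p_s(1−p_s)).

The σ²_k are estimated by average-information REML (EM first step, AI
Newton updates, step-halving, components floored at a small positive
value). Component shares h²_k = σ²_k / Σσ² carry delta-method standard
errors; single components are tested with the boundary likelihood-ratio
mixture ½χ²₀ + ½χ²₁.

A partition with m_k of M SNPs is *enriched* when its observed h²
exceeds the share expected under a uniform per-SNP architecture,

    expected h²_k = (m_k / M) · h²_total,   enrichment = h²_obs / expected,

significant when the expected value falls outside the 95% CI of the
observed estimate. Subset estimates are pooled by inverse-variance
fixed-effects meta-analysis; subset sizes can be chosen with the GREML
power formula var(ĥ²) = 2/(n² v), v the off-diagonal GRM variance.

For prediction, marginal GWAS effects β̂ (standardized scale) are jointly
re-shrunken with a reference LD matrix R by solving

    (n·R + λI) u = n·β̂,   λ = m (1/h² − 1),

and the adjusted effects u are summed over standardized dosages per
partition (summary-based BLUP polygenic scores), then tested in a
validation cohort by OLS with ancestry principal components.

## Worked example

`examples/02_partitioned_heritability.py` simulates 1,200 samples ×
2,400 SNPs with known partition heritabilities (2% / 10% / 15%, exact
in-sample rescaling) and fits the 3-component model:

```
converged in 7 iterations, logL = -600.41
  h2_coding =  0.029 (SE 0.020)   truth 0.020
  h2_buffer =  0.080 (SE 0.026)   truth 0.100
  h2_rest   =  0.147 (SE 0.037)   truth 0.150
  residual  =  0.744
LRT for the buffer component: 18.22, boundary p = 0.0000
```

Each estimate covers its generating truth within about two standard
errors, and the likelihood-ratio test firmly rejects a model without the
buffer component. The other scripts in `examples/` walk through QC and
partitioning, enrichment with subset meta-analysis, gene-set overlap
statistics, and cross-cohort SBLUP prediction; each prints the numbers
it computes and one line on how to read them.

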