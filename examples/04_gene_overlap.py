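"""Gene-based association and gene-set overlap statistics.

Runs the LOCO mixed-model scan, aggregates SNP p-values to genes
(Bonferroni min-p in a 10 kb window), applies BH-FDR, and asks whether
the a-priori gene set overlaps the associated genes more than chance:
Fisher's exact test on the gene background, Jaccard similarity, and a
permutation test of the gene-level signal.
"""

from partherit import (
    SimConfig, build_partition, covariate_design, fisher_overlap, gene_minp,
    jaccard, mlma_loco, permutation_signal_test, simulate_cohort,
)

cfg = SimConfig(
    n_samples=1000, n_snps=3000, n_chromosomes=3, n_genes=60, n_geneset_genes=15,
    gene_length_bp=10_000, h2_coding=0.15, h2_buffer=0.0, h2_rest=0.02,
    buffer_kb_truth=0.0, causal_fraction=0.5, seed=19,
)
cohort = simulate_cohort(cfg)

gwas = mlma_loco(cohort.panel, cohort.phenotype, covariate_design(cohort.covariates))
genes = gene_minp(gwas, cohort.genes, window_kb=10)
hits = set(genes.loc[genes["p_adj"] < 0.05, "symbol"])
geneset = {g.symbol for g in cohort.genes if g.in_geneset}
background = {g.symbol for g in cohort.genes}
print(f"{len(hits)} genes associated at FDR 5% of {len(genes)} scored")

res = fisher_overlap(geneset, hits, background)
print(f"gene-set overlap: a={res.table.a} b={res.table.b} c={res.table.c} "
      f"d={res.table.d}")
print(f"odds ratio {res.odds_ratio:.2f} (exact CI {res.ci[0]:.2f}-{res.ci[1]:.2f}), "
      f"Fisher p = {res.p:.3g}; Jaccard = {jaccard(geneset, hits):.3f}")

perm = permutation_signal_test(geneset, genes, n_perm=999, seed=19)
print(f"gene-set mean -log10 p = {perm['statistic']:.2f} vs null mean "
      f"{perm['null_mean']:.2f}; permutation p = {perm['p']:.3g}")
print("Causal variants sit in the gene set's coding regions, so the set "
      "should be enriched among hits and carry excess gene-level signal.")
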