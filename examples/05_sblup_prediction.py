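"""Partitioned SBLUP polygenic prediction in a held-out cohort.

Trains a LOCO mixed-model GWAS in a discovery cohort whose causal
variants are concentrated in the gene set's coding regions, re-shrinks
the marginal effects jointly with a reference-panel LD matrix
(lambda = m (1/h2 - 1)), scores an independent validation cohort per SNP
partition, and tests each score against the phenotype with six ancestry
PCs as covariates.
"""

import numpy as np
import pandas as pd

from partherit import (
    SblupConfig, SimConfig, build_partition, covariate_design, ld_blocks,
    mlma_loco, pgs_association, sblup_adjust, score, simulate_cohort,
    simulate_genotypes, simulate_phenotype, standardize_effects, top_pcs,
)

base = dict(
    n_snps=1500, n_chromosomes=3, block_size_snps=5, within_block_corr=0.5,
    n_genes=15, n_geneset_genes=15, gene_length_bp=20_000,
    h2_coding=0.20, h2_buffer=0.0, h2_rest=0.05, buffer_kb_truth=0.0,
    causal_fraction=0.5, frequency_seed=42,
)
discovery = simulate_cohort(SimConfig(n_samples=600, seed=43, **base))
assignment = build_partition(discovery.genes, discovery.panel, 0.0)

cfg_val = SimConfig(n_samples=500, seed=44, **base)
val_panel = simulate_genotypes(cfg_val)
validation = simulate_phenotype(
    val_panel, assignment, cfg_val, genes=discovery.genes,
    architecture=discovery.truth["partitions"],  # shared causal biology
)
reference = simulate_genotypes(SimConfig(n_samples=500, seed=45, **base))

gwas = mlma_loco(discovery.panel, discovery.phenotype,
                 covariate_design(discovery.covariates))
betas = gwas.table.set_index("snp").loc[discovery.panel.snp_ids, "beta"].to_numpy()
beta_std = standardize_effects(betas, discovery.panel.allele_freq())
adjusted = sblup_adjust(
    beta_std, ld_blocks(reference, window_kb=1000), n_gwas=600,
    cfg=SblupConfig(h2_snp=0.25, m_total=1500),
)

scores = pd.DataFrame({
    "coding": score(val_panel, adjusted, assignment.indices("coding")),
    "rest": score(val_panel, adjusted, assignment.indices("rest")),
    "all": score(val_panel, adjusted),
})
covars = np.column_stack([np.ones(500), top_pcs(val_panel, 6)])
result = pgs_association(scores, validation.phenotype, covars)
print(result.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("Incremental R2 is the score's variance explained beyond the PCs in "
      "the held-out cohort: the coding-partition score should predict "
      "strongly, the rest partition weakly — the cross-cohort transfer of "
      "the gene-set signal.")
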