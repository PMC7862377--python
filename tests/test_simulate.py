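"""Generator properties: determinism, LD calibration, exact variance targets."""

import numpy as np
import pytest

from partherit import (
    SimConfig,
    build_partition,
    simulate_cohort,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_phenotype,
)
from partherit.errors import ConfigurationError


def test_seed_reproducibility_is_bit_identical():
    cfg = SimConfig(n_samples=120, n_snps=300, n_genes=8, n_geneset_genes=4, seed=11)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    assert np.array_equal(a.panel.dosages, b.panel.dosages)
    assert np.array_equal(a.phenotype, b.phenotype)
    assert [(g.symbol, g.start_bp, g.in_geneset) for g in a.genes] == [
        (g.symbol, g.start_bp, g.in_geneset) for g in b.genes
    ]


def test_dosages_are_diploid_counts(small_cohort):
    assert set(np.unique(small_cohort.panel.dosages)) <= {0.0, 1.0, 2.0}


def test_maf_within_configured_range(small_cohort):
    maf = small_cohort.panel.maf()
    # block-level targets are in [0.05, 0.5]; allow binomial sampling error
    assert maf.min() > 0.05 - 3 * np.sqrt(0.05 * 0.95 / (2 * 300))
    assert maf.max() <= 0.5


def _adjacent_corrs(panel, block_size, n_snps):
    x = panel.dosages
    cors = []
    for b in range(0, n_snps, block_size):
        for j in range(b, b + block_size - 1):
            cors.append(np.corrcoef(x[:, j], x[:, j + 1])[0, 1])
    return np.asarray(cors)


def test_zero_block_corr_gives_independent_adjacent_snps():
    n = 4000
    cfg = SimConfig(
        n_samples=n, n_snps=100, n_chromosomes=1, block_size_snps=10,
        within_block_corr=0.0, n_genes=4, n_geneset_genes=2, seed=5,
    )
    panel = simulate_genotypes(cfg)
    cors = _adjacent_corrs(panel, 10, 100)
    assert np.mean(np.abs(cors)) < 3.0 / np.sqrt(n)


def test_block_corr_calibration_hits_target():
    # Monte-Carlo check of the thresholded latent-AR construction: with the
    # tetrachoric calibration the *genotype* correlation matches the target.
    cfg = SimConfig(
        n_samples=5000, n_snps=500, n_chromosomes=1, block_size_snps=25,
        within_block_corr=0.8, n_genes=4, n_geneset_genes=2, seed=3,
    )
    panel = simulate_genotypes(cfg)
    cors = _adjacent_corrs(panel, 25, 500)
    assert 0.7 < cors.mean() < 0.9


def test_cross_block_snps_are_uncorrelated():
    cfg = SimConfig(
        n_samples=4000, n_snps=100, n_chromosomes=1, block_size_snps=10,
        within_block_corr=0.8, n_genes=4, n_geneset_genes=2, seed=9,
    )
    x = simulate_genotypes(cfg).dosages
    boundary = [np.corrcoef(x[:, b - 1], x[:, b])[0, 1] for b in range(10, 100, 10)]
    assert np.mean(np.abs(boundary)) < 3.0 / np.sqrt(4000)


def test_gene_placement_disjoint_and_flag_count():
    cfg = SimConfig(n_samples=50, n_snps=600, n_genes=30, n_geneset_genes=12, seed=2)
    genes = simulate_gene_annotation(cfg)
    assert len(genes) == 30
    assert sum(g.in_geneset for g in genes) == 12
    by_chrom = {}
    for g in genes:
        assert 1 <= g.start_bp <= g.stop_bp <= cfg.chrom_length_bp
        by_chrom.setdefault(g.chrom, []).append((g.start_bp, g.stop_bp))
    for ivals in by_chrom.values():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            assert e1 < s2  # strictly disjoint


def test_gene_placement_fails_when_genome_too_small():
    cfg = SimConfig(n_samples=50, n_snps=300, n_genes=60, gene_length_bp=20_000, seed=2)
    with pytest.raises(ConfigurationError):
        simulate_gene_annotation(cfg)


def test_exact_rescaling_hits_variance_targets(small_cohort):
    parts = small_cohort.truth["partitions"]
    for label, target in [("coding", 0.005), ("buffer", 0.030), ("rest", 0.050)]:
        assert abs(parts[label]["h2_realized"] - target) < 1e-10
    assert abs(small_cohort.truth["sigma2_e"] - (1 - 0.085)) < 1e-10


def test_null_architecture_gives_pure_noise_phenotype():
    cfg = SimConfig(
        n_samples=500, n_snps=300, h2_coding=0, h2_buffer=0, h2_rest=0,
        n_genes=6, n_geneset_genes=3, covariate_effects={}, seed=21,
    )
    co = simulate_cohort(cfg)
    assert all(p["h2_realized"] == 0.0 for p in co.truth["partitions"].values())
    assert abs(np.var(co.phenotype) - 1.0) < 1e-10  # exact noise rescaling
    # no SNP should show a strong marginal association
    z = co.panel.standardized()
    r = (z.T @ (co.phenotype - co.phenotype.mean())) / (500 * co.phenotype.std())
    assert np.max(np.abs(r)) < 6.0 / np.sqrt(500)


def test_empty_partition_with_positive_target_raises(small_cohort):
    cfg = SimConfig(n_samples=300, n_snps=1200, seed=1)
    panel = small_cohort.panel
    genes = small_cohort.genes
    assignment = build_partition(genes, panel, 0.0)  # no buffer SNPs
    if (assignment.labels == "buffer").sum() == 0:
        with pytest.raises(ConfigurationError):
            simulate_phenotype(panel, assignment, cfg)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimConfig(h2_coding=0.5, h2_buffer=0.4, h2_rest=0.2)
    with pytest.raises(ConfigurationError):
        SimConfig(within_block_corr=1.0)
    with pytest.raises(ConfigurationError):
        SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ConfigurationError):
        SimConfig(n_samples=0)


def test_architecture_replay_reuses_causal_snps():
    base = dict(n_samples=200, n_snps=300, n_genes=8, n_geneset_genes=4,
                frequency_seed=77)
    cfg1 = SimConfig(seed=1, **base)
    co1 = simulate_cohort(cfg1)
    assignment = build_partition(co1.genes, co1.panel, cfg1.buffer_kb_truth)
    cfg2 = SimConfig(seed=2, **base)
    panel2 = simulate_genotypes(cfg2)
    co2 = simulate_phenotype(
        panel2, assignment, cfg2, architecture=co1.truth["partitions"]
    )
    for lab in ("coding", "buffer", "rest"):
        assert (co2.truth["partitions"][lab]["causal_snps"]
                == co1.truth["partitions"][lab]["causal_snps"])
    assert not np.array_equal(co1.phenotype, co2.phenotype)


def test_save_cohort_round_trips_through_standard_formats(tmp_path):
    from partherit import read_genes, read_plink, save_cohort
    import pandas as pd
    import yaml

    cfg = SimConfig(n_samples=40, n_snps=120, n_genes=8, n_geneset_genes=4, seed=13)
    co = simulate_cohort(cfg)
    paths = save_cohort(co, tmp_path)
    back = read_plink(paths["plink"])
    assert np.array_equal(back.dosages, co.panel.dosages, equal_nan=True)
    pheno = pd.read_csv(paths["pheno"], sep="\t")
    np.testing.assert_allclose(pheno["pheno"], co.phenotype)
    genes = read_genes(paths["genes"])
    assert sum(g.in_geneset for g in genes) == 4
    truth = yaml.safe_load(open(paths["truth"]))
    assert set(truth["partitions"]) == {"coding", "buffer", "rest"}
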