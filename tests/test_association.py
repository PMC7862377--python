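"""Mixed-model association, gene min-p aggregation, BH-FDR."""

import numpy as np
import pytest

from partherit import (
    GeneInterval,
    SimConfig,
    bh_fdr,
    compute_grm,
    covariate_design,
    gene_minp,
    mlma_loco,
    simulate_cohort,
)
from partherit.association import GwasResults, _chi2_scan
import pandas as pd


def test_null_variance_limit_equals_partialled_ols():
    # with sigma2_g at zero, V is proportional to I and the mixed-model
    # scan reduces to OLS with covariates projected out
    cfg = SimConfig(n_samples=200, n_snps=300, h2_coding=0, h2_buffer=0, h2_rest=0,
                    n_genes=8, n_geneset_genes=4, seed=31)
    co = simulate_cohort(cfg)
    X = covariate_design(co.covariates)
    y = co.phenotype
    n = 200
    sigma_e = 0.9
    vinv = np.eye(n) / sigma_e
    vx = vinv @ X
    P = vinv - vx @ np.linalg.solve(X.T @ vx, vx.T)
    x_imp = co.panel.imputed()
    w = x_imp - x_imp.mean(axis=0)
    beta, se, p = _chi2_scan(P, y, w)
    # oracle: partialled OLS per SNP (scale of V cancels in the slope)
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    w_r = w - Q @ (Q.T @ w)
    denom = np.einsum("ij,ij->j", w_r, w_r)
    beta_ols = (w_r.T @ y_r) / denom
    np.testing.assert_allclose(beta, beta_ols, rtol=1e-8)
    np.testing.assert_allclose(se, np.sqrt(sigma_e / denom), rtol=1e-8)


def test_large_effect_snp_attains_min_p():
    cfg = SimConfig(n_samples=800, n_snps=400, n_chromosomes=2,
                    h2_coding=0, h2_buffer=0, h2_rest=0,
                    n_genes=8, n_geneset_genes=4, covariate_effects={}, seed=17)
    co = simulate_cohort(cfg)
    z = co.panel.standardized()
    y = co.phenotype + np.sqrt(0.05 / 0.95) * z[:, 123]  # SNP explains ~5%
    gw = mlma_loco(co.panel, y, np.ones((800, 1)))
    tab = gw.table
    assert tab.loc[tab["p"].idxmin(), "snp"] == co.panel.snp_ids[123]


def test_loco_excludes_proximal_contamination():
    # excluding the causal SNP's chromosome from the GRM must increase its
    # test statistic relative to a GRM that absorbs the causal signal
    cfg = SimConfig(n_samples=500, n_snps=600, n_chromosomes=2,
                    h2_coding=0, h2_buffer=0, h2_rest=0,
                    n_genes=8, n_geneset_genes=4, covariate_effects={}, seed=23)
    co = simulate_cohort(cfg)
    z = co.panel.standardized()
    y = co.phenotype + np.sqrt(0.08 / 0.92) * z[:, 10]  # causal on chromosome 1
    X = np.ones((500, 1))
    gw = mlma_loco(co.panel, y, X)
    chi2_loco = (gw.table.loc[10, "beta"] / gw.table.loc[10, "se"]) ** 2

    from partherit import VarianceComponentModel, fit_greml
    grm_all = compute_grm(co.panel)
    fit = fit_greml(VarianceComponentModel([grm_all], X, y))
    V = fit.sigma2[0] * grm_all.matrix + fit.sigma2[1] * np.eye(500)
    vinv = np.linalg.inv(V)
    vx = vinv @ X
    P = vinv - vx @ np.linalg.solve(X.T @ vx, vx.T)
    x_imp = co.panel.imputed()
    w = (x_imp - x_imp.mean(axis=0))[:, [10]]
    beta, se, _ = _chi2_scan(P, y, w)
    chi2_in = (beta[0] / se[0]) ** 2
    assert chi2_loco > chi2_in


def test_single_chromosome_falls_back_with_warning():
    cfg = SimConfig(n_samples=100, n_snps=100, n_chromosomes=1,
                    n_genes=4, n_geneset_genes=2, seed=3)
    co = simulate_cohort(cfg)
    with pytest.warns(UserWarning, match="single chromosome"):
        gw = mlma_loco(co.panel, co.phenotype, np.ones((100, 1)))
    assert not gw.loco


def _toy_gwas(positions, pvals, chrom="1"):
    tab = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "a1": "A",
            "beta": 0.0,
            "se": 1.0,
            "p": pvals,
            "n": 100,
        }
    )
    return GwasResults(table=tab, loco=True)


def test_gene_minp_examples():
    gw = _toy_gwas([5000], [0.01])
    genes = [GeneInterval("G1", "1", 1000, 8000, in_geneset=True)]
    out = gene_minp(gw, genes, window_kb=10)
    assert out.loc[0, "p"] == pytest.approx(0.01)

    gw = _toy_gwas(list(range(1000, 11000, 1000)), [0.001] + [0.5] * 9)
    genes = [GeneInterval("G1", "1", 1, 20000, in_geneset=True)]
    out = gene_minp(gw, genes, window_kb=0)
    assert out.loc[0, "n_snps"] == 10
    assert out.loc[0, "p"] == pytest.approx(0.01)


def test_gene_minp_matches_window_scan_oracle(small_cohort):
    rng = np.random.default_rng(5)
    panel = small_cohort.panel
    pvals = rng.uniform(size=panel.n_snps)
    tab = panel.snp_meta[["snp", "chrom", "pos", "a1"]].copy()
    tab["beta"], tab["se"], tab["p"], tab["n"] = 0.0, 1.0, pvals, 300
    gw = GwasResults(table=tab, loco=True)
    out = gene_minp(gw, small_cohort.genes, window_kb=10).set_index("symbol")
    for g in small_cohort.genes:
        mask = (
            (tab["chrom"].astype(str) == g.chrom)
            & (tab["pos"] >= g.start_bp - 10000)
            & (tab["pos"] <= g.stop_bp + 10000)
        )
        if mask.sum() == 0:
            assert g.symbol not in out.index
        else:
            expect = min(1.0, mask.sum() * pvals[mask.to_numpy()].min())
            assert out.loc[g.symbol, "p"] == pytest.approx(expect)


def test_genes_without_snps_are_omitted():
    gw = _toy_gwas([5000], [0.5])
    genes = [GeneInterval("FAR", "1", 10**6, 10**6 + 100, in_geneset=True)]
    assert len(gene_minp(gw, genes)) == 0


def _bh_naive(p):
    m = len(p)
    adj = np.empty(m)
    order = np.argsort(p)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def test_bh_fdr_examples_and_oracle():
    np.testing.assert_allclose(
        bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_fdr([0.2]), [0.2])
    rng = np.random.default_rng(9)
    p = rng.uniform(size=200)
    np.testing.assert_allclose(bh_fdr(p), _bh_naive(p), rtol=1e-12)


def test_bh_fdr_permutation_equivariance():
    rng = np.random.default_rng(10)
    p = rng.uniform(size=50)
    perm = rng.permutation(50)
    np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))
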