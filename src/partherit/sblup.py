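"""Summary-based BLUP effect adjustment and partitioned polygenic scores.

Marginal GWAS effects (on the standardized-genotype scale) are jointly
re-shrunken using a reference-panel LD matrix by solving, per chromosome,

    (n_gwas * R + lambda I) u = n_gwas * beta_hat,

with lambda = m_total * (1 / h2_snp - 1).  The adjusted effects are then
summed over standardized dosages to give per-sample scores, separately
for each SNP partition, and the scores are tested against the phenotype
in a validation cohort by OLS with ancestry principal components as
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel

__all__ = ["SblupConfig", "PgsResult", "ld_blocks", "sblup_adjust", "score",
           "pgs_association", "standardize_effects"]


@dataclass
class SblupConfig:
    """Shrinkage configuration; lambda = m_total (1/h2_snp - 1)."""

    h2_snp: float
    m_total: int
    ld_window_kb: float = 1000.0
    ld_ridge: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.h2_snp < 1.0:
            raise ValueError("h2_snp must lie strictly in (0, 1)")
        if self.m_total <= 0:
            raise ValueError("m_total must be positive")

    @property
    def lam(self) -> float:
        return self.m_total * (1.0 / self.h2_snp - 1.0)


@dataclass
class PgsResult:
    """Partitioned polygenic scores and their validation associations."""

    scores: pd.DataFrame                 # one column per partition
    association: pd.DataFrame = field(default=None)  # beta, se, p, r2_inc per partition


def ld_blocks(reference: GenotypePanel, window_kb: float = 1000.0) -> dict:
    """Banded LD (correlation) matrices per chromosome from a reference panel.

    Correlations between SNPs farther apart than ``window_kb`` are set to
    zero; diagonals are 1 (monomorphic reference SNPs get an identity
    row).  Returns ``{chrom: (snp_indices, R)}`` with indices into the
    reference panel's SNP order.
    """
    window = window_kb * 1000.0
    chroms = reference.snp_meta["chrom"].astype(str).to_numpy()
    positions = reference.snp_meta["pos"].to_numpy(dtype=float)
    blocks = {}
    for c in pd.unique(chroms):
        idx = np.nonzero(chroms == c)[0]
        x = reference.imputed(idx)
        x = x - x.mean(axis=0)
        sd = x.std(axis=0)
        bad = sd == 0
        x[:, ~bad] /= sd[~bad]
        r = (x.T @ x) / x.shape[0]  # empirical correlation
        r[bad, :] = 0.0
        r[:, bad] = 0.0
        np.fill_diagonal(r, 1.0)
        pos = positions[idx]
        far = np.abs(pos[:, None] - pos[None, :]) > window
        r[far] = 0.0
        blocks[str(c)] = (idx, r)
    return blocks


def sblup_adjust(betas, ld: dict, n_gwas: int, cfg: SblupConfig) -> np.ndarray:
    """Joint shrinkage of marginal standardized effects via reference LD.

    ``betas`` must be aligned with the reference panel SNP order used to
    build ``ld``.  Solves (n (R + ridge I) + lambda I) u = n beta per
    chromosome block.
    """
    betas = np.asarray(betas, dtype=float)
    u = np.full(betas.shape, np.nan)
    lam = cfg.lam
    for chrom, (idx, r) in ld.items():
        lhs = n_gwas * (r + cfg.ld_ridge * np.eye(r.shape[0])) + lam * np.eye(r.shape[0])
        try:
            u[idx] = np.linalg.solve(lhs, n_gwas * betas[idx])
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"SBLUP system for chromosome {chrom} could not be solved"
            ) from err
    if np.isnan(u).any():
        raise ValueError("LD blocks do not cover all SNPs with effects")
    return u


def standardize_effects(beta_allelic, freq) -> np.ndarray:
    """Per-allele effect sizes to the standardized-genotype scale."""
    freq = np.asarray(freq, dtype=float)
    return np.asarray(beta_allelic, dtype=float) * np.sqrt(2.0 * freq * (1.0 - freq))


def score(panel: GenotypePanel, effects, snp_indices=None) -> np.ndarray:
    """Polygenic score: effects summed over standardized dosages.

    ``effects`` is aligned with the panel SNP order; ``snp_indices``
    restricts the sum to a partition (default: all SNPs).
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size != panel.n_snps:
        raise ValueError("effects must align with the panel SNPs")
    if snp_indices is None:
        snp_indices = np.arange(panel.n_snps)
    snp_indices = np.asarray(snp_indices)
    if snp_indices.dtype == bool:
        snp_indices = np.nonzero(snp_indices)[0]
    z = panel.standardized(snp_indices)
    return z @ effects[snp_indices]


def pgs_association(scores, phenotype, covariates) -> pd.DataFrame:
    """OLS of phenotype on each score column plus covariates.

    ``covariates`` is the full design (intercept + e.g. six ancestry
    PCs); the report contains the score beta, SE, p, and the incremental
    R^2 over the covariate-only model.
    """
    y = np.asarray(phenotype, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate design is rank deficient (duplicate columns?)")
    if isinstance(scores, pd.DataFrame):
        names, cols = list(scores.columns), [scores[c].to_numpy() for c in scores.columns]
    else:
        names, cols = ["score"], [np.asarray(scores, dtype=float)]

    def _r2(design):
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        tot = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum(resid ** 2) / tot

    r2_cov = _r2(C)
    rows = []
    for name, s in zip(names, cols):
        design = np.column_stack([s, C])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        dof = y.size - design.shape[1]
        s2 = np.sum(resid ** 2) / dof
        xtx_inv = np.linalg.inv(design.T @ design)
        se = float(np.sqrt(s2 * xtx_inv[0, 0]))
        t = coef[0] / se
        p = float(2.0 * stats.t.sf(abs(t), dof))
        rows.append({"partition": name, "beta": float(coef[0]), "se": se,
                     "p": p, "r2_inc": float(_r2(design) - r2_cov)})
    return pd.DataFrame(rows)
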