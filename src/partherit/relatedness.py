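"""Genomic relatedness matrices, relatedness pruning, and principal components.

The GRM entry for samples j, k over m SNPs is

    A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with p_i the sample A1 frequency and missing dosages mean-imputed.  The
divisor is the fixed SNP count m (not per-pair non-missing counts); the
two coincide when missingness is zero, the situation after QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .panel import GenotypePanel


@dataclass
class GRM:
    """Symmetric relatedness matrix with its sample ids and SNP count."""

    matrix: np.ndarray
    sample_ids: list
    m_snps: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM matrix must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix")
        if self.m_snps <= 0:
            raise ValueError("m_snps must be positive")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_grm(panel: GenotypePanel, snp_indices=None) -> GRM:
    """GRM over the given SNP subset (default: all polymorphic SNPs).

    Monomorphic SNPs are excluded from the divisor; a subset that is
    entirely monomorphic raises ``ValueError``.
    """
    if snp_indices is None:
        snp_indices = np.arange(panel.n_snps)
    snp_indices = np.asarray(snp_indices)
    if snp_indices.dtype == bool:
        snp_indices = np.nonzero(snp_indices)[0]
    if snp_indices.size == 0:
        raise ValueError("SNP subset is empty")
    x = panel.imputed(snp_indices)
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("SNP subset contains only monomorphic SNPs")
    x = x[:, poly]
    p = p[poly]
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = z.shape[1]
    a = (z @ z.T) / m
    return GRM(matrix=a, sample_ids=list(panel.sample_ids), m_snps=m)


def offdiag_variance(grm: GRM) -> float:
    """Unbiased sample variance of the n(n-1)/2 off-diagonal GRM entries.

    This is the quantity the GREML power calculation consumes: the
    sampling variance of a heritability estimate scales as
    2 / (n^2 * var_offdiag).
    """
    if grm.n < 2:
        raise ValueError("need at least two samples")
    off = grm.matrix[np.tril_indices(grm.n, k=-1)]
    return float(np.var(off, ddof=1))


def relatedness_prune(grm: GRM, cutoff: float = 0.05) -> list:
    """Greedy pruning so that no remaining pair exceeds ``cutoff``.

    While any off-diagonal entry exceeds the cutoff, take the worst
    (largest) offending pair and drop whichever member participates in
    more over-cutoff pairs, breaking ties toward the later sample id.
    The default cutoff 0.05 approximates "no closer than second cousins".
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = grm.matrix.copy()
    np.fill_diagonal(a, 0.0)
    active = np.ones(grm.n, dtype=bool)
    while True:
        masked = np.where(np.outer(active, active), a, 0.0)
        over = masked > cutoff
        if not over.any():
            break
        j, k = np.unravel_index(np.argmax(masked), masked.shape)
        deg_j, deg_k = over[j].sum(), over[k].sum()
        drop = k if (deg_k > deg_j or (deg_k == deg_j and k > j)) else j
        active[drop] = False
        if active.sum() == 1:
            warnings.warn("relatedness pruning left a single sample")
            break
    return [sid for sid, keep in zip(grm.sample_ids, active) if keep]


def top_pcs(panel: GenotypePanel, k: int) -> np.ndarray:
    """Leading principal-component scores of the standardized dosages.

    Returns the n x k matrix U_k S_k from the thin SVD of the standardized
    genotype matrix, with the deterministic sign convention that each
    component's largest-magnitude SNP loading is positive.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    n = panel.n_samples
    if k == 0:
        return np.empty((n, 0))
    z = panel.standardized()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(k, s.size)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores
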