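"""Heritability enrichment, power-based subsetting, and meta-analysis.

The enrichment of a SNP category compares its observed heritability share
with what a uniform per-SNP distribution of the genome-wide h2 would
give:

    expected h2_k = (m_k / M) * h2_total,    enrichment = h2_obs / expected.

Significance uses the confidence-interval exclusion rule: the category is
enriched (or depleted) when the expected value falls outside the 95% CI
of the observed estimate, i.e. |h2_obs - expected| > 1.96 * SE(h2_obs).
An alternative z-ratio rule (enrichment statistic > 1.96) can be selected
explicitly but is not the default.

Sample subsets of equal statistical footing are built by round-robin
allocation within phenotype quartiles, and per-subset estimates are
pooled by fixed-effects inverse-variance meta-analysis.  The GREML power
calculation uses var(h2_hat) = 2 / (n^2 * v) with v the variance of the
off-diagonal GRM entries, and a one-degree noncentral chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EnrichmentResult", "MetaEstimate", "expected_h2", "enrichment",
           "fixed_effects_meta", "percent_total", "greml_power", "greml_h2_se",
           "quartile_split"]


@dataclass
class EnrichmentResult:
    label: str
    m_k: int
    M: int
    h2_obs: float
    se_obs: float
    h2_exp: float
    enrichment: float
    significant: bool
    rule: str = "ci"


@dataclass
class MetaEstimate:
    estimate: float
    se: float
    estimates: tuple
    ses: tuple

    @property
    def z(self) -> float:
        return self.estimate / self.se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


def expected_h2(m_k: int, M: int, h2_total: float) -> float:
    """Heritability expected for m_k of M SNPs under a uniform per-SNP h2."""
    if not 0 < m_k <= M:
        raise ValueError("require 0 < m_k <= M")
    if not 0.0 <= h2_total <= 1.0:
        raise ValueError("h2_total must lie in [0, 1]")
    return (m_k / M) * h2_total


def enrichment(
    h2_obs: float,
    se_obs: float,
    m_k: int,
    M: int,
    h2_total: float,
    label: str = "",
    rule: str = "ci",
) -> EnrichmentResult:
    """Observed-vs-expected enrichment of one SNP category.

    ``rule="ci"`` flags significance when the expected h2 falls outside
    the 95% CI of the observed estimate; ``rule="z"`` flags when the
    enrichment ratio itself exceeds 1.96.
    """
    if m_k == 0:
        raise ValueError("enrichment undefined for an empty SNP category")
    if se_obs <= 0:
        raise ValueError("se_obs must be positive")
    h2_exp = expected_h2(m_k, M, h2_total)
    ratio = h2_obs / h2_exp
    if rule == "ci":
        significant = abs(h2_obs - h2_exp) > 1.96 * se_obs
    elif rule == "z":
        significant = ratio > 1.96
    else:
        raise ValueError(f"unknown significance rule {rule!r}")
    return EnrichmentResult(
        label=label, m_k=int(m_k), M=int(M), h2_obs=h2_obs, se_obs=se_obs,
        h2_exp=h2_exp, enrichment=ratio, significant=bool(significant), rule=rule,
    )


def fixed_effects_meta(estimates, ses) -> MetaEstimate:
    """Inverse-variance weighted fixed-effects pooling."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size == 0 or est.shape != se.shape:
        raise ValueError("estimates and ses must be equal-length and non-empty")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    return MetaEstimate(estimate=pooled, se=pooled_se,
                        estimates=tuple(est), ses=tuple(se))


def percent_total(meta_component: MetaEstimate, meta_total: MetaEstimate) -> float:
    """Pooled component heritability as a percentage of the pooled total."""
    if meta_total.estimate == 0:
        raise ValueError("total heritability is zero")
    return 100.0 * meta_component.estimate / meta_total.estimate


def greml_h2_se(n: int, v_offdiag: float) -> float:
    """Approximate SE of a GREML h2 estimate: sqrt(2 / (n^2 v))."""
    if n < 2 or v_offdiag <= 0:
        raise ValueError("need n >= 2 and positive off-diagonal variance")
    return float(np.sqrt(2.0 / (n ** 2 * v_offdiag)))


def greml_power(n: int, v_offdiag: float, h2: float, alpha: float = 0.05) -> float:
    """Power of GREML to detect heritability h2 at significance alpha.

    Uses the GCTA power-calculator convention: the test statistic is
    noncentral chi-square with 1 df and NCP = h2^2 / var(h2_hat), with
    var(h2_hat) = 2 / (n^2 * v_offdiag).
    """
    se = greml_h2_se(n, v_offdiag)
    ncp = (h2 / se) ** 2
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else float(alpha)


def quartile_split(phenotype, k_subsets: int, seed: int) -> np.ndarray:
    """Allocate samples to k subsets balanced on phenotype quartiles.

    Within each quartile of the phenotype distribution, samples are
    shuffled and dealt round-robin to the subsets (rotating the starting
    subset per quartile), so every subset receives the same quartile
    composition up to one sample.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if k_subsets < 1 or k_subsets > n:
        raise ValueError("k_subsets must be in [1, n]")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    quartile = np.empty(n, dtype=int)
    quartile[order] = (4 * np.arange(n)) // n
    out = np.empty(n, dtype=int)
    for q in range(4):
        members = np.nonzero(quartile == q)[0]
        rng.shuffle(members)
        out[members] = (np.arange(members.size) + q) % k_subsets
    return out
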