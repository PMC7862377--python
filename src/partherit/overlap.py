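"""Gene-set overlap statistics.

Cross-study/cross-species comparisons of gene lists: Jaccard similarity,
Fisher's exact enrichment of an a-priori gene set among association hits
against a homolog background, and a permutation test of whether the gene
set carries more gene-level association signal than random same-size
draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or

__all__ = ["OverlapTable", "FisherOverlap", "jaccard", "fisher_overlap",
           "permutation_signal_test", "ranksum_signal_comparison"]


@dataclass
class OverlapTable:
    """2x2 classification of a background gene universe."""

    a: int  # in gene set and associated
    b: int  # gene set only
    c: int  # associated only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def background(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class FisherOverlap:
    table: OverlapTable
    odds_ratio: float           # sample OR = ad / bc
    conditional_or: float       # conditional MLE, stored secondarily
    p: float
    ci: tuple


def jaccard(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def fisher_overlap(geneset, assoc_genes, background) -> FisherOverlap:
    """Fisher's exact test of gene-set / association-hit overlap.

    The headline ratio is the sample odds ratio (a d)/(b c); the
    conditional-MLE odds ratio and its exact CI are computed alongside.
    The two-sided p sums hypergeometric probabilities no larger than the
    observed table's.
    """
    geneset, assoc, bg = set(geneset), set(assoc_genes), set(background)
    if not geneset <= bg or not assoc <= bg:
        raise ValueError("gene set and association hits must be subsets of the background")
    a = len(geneset & assoc)
    b = len(geneset - assoc)
    c = len(assoc - geneset)
    d = len(bg) - a - b - c
    return fisher_from_counts(a, b, c, d)


def fisher_from_counts(a: int, b: int, c: int, d: int) -> FisherOverlap:
    """Fisher overlap statistics from the four 2x2 cell counts."""
    table = OverlapTable(a, b, c, d)
    arr = table.as_array()
    if b * c == 0:
        sample_or = 0.0 if a * d == 0 else np.inf
    else:
        sample_or = (a * d) / (b * c)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    res = _conditional_or(arr, kind="conditional")
    ci = res.confidence_interval(0.95)
    return FisherOverlap(
        table=table,
        odds_ratio=float(sample_or),
        conditional_or=float(res.statistic),
        p=float(p),
        ci=(float(ci.low), float(ci.high)),
    )


def permutation_signal_test(
    geneset,
    gene_stats: pd.DataFrame,
    n_perm: int,
    seed: int,
) -> dict:
    """Permutation test of gene-set association signal.

    The statistic is the mean -log10 gene p over gene-set genes present
    in ``gene_stats``; the null draws ``n_perm`` random same-size gene
    sets from all scored genes.  The empirical p uses the add-one rule
    (1 + #{null >= observed}) / (n_perm + 1).
    """
    symbols = gene_stats["symbol"].to_numpy()
    logp = -np.log10(gene_stats["p"].to_numpy(dtype=float))
    members = np.isin(symbols, list(set(geneset)))
    k = int(members.sum())
    if k == 0:
        raise ValueError("no gene-set gene is present in gene_stats")
    observed = float(logp[members].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = logp[rng.choice(logp.size, size=k, replace=False)].mean()
    p_emp = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return {"statistic": observed, "p": p_emp, "n_genes": k,
            "null_mean": float(null.mean())}


def ranksum_signal_comparison(gene_stats: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Pairwise two-sided rank-sum comparison of gene-level signal.

    For each pair of named gene groups (e.g. genes implicated in
    different model organisms) the -log10 gene p-values are compared with
    the Mann-Whitney U test; p-values are BH-adjusted across pairs.
    """
    from itertools import combinations

    from .association import bh_fdr

    symbols = gene_stats["symbol"].to_numpy()
    logp = -np.log10(gene_stats["p"].to_numpy(dtype=float))
    per_group = {}
    for name, members in groups.items():
        mask = np.isin(symbols, list(set(members)))
        if mask.sum() == 0:
            raise ValueError(f"group {name!r} has no scored genes")
        per_group[name] = logp[mask]
    rows = []
    for a, b in combinations(per_group, 2):
        stat, p = stats.mannwhitneyu(
            per_group[a], per_group[b], alternative="two-sided"
        )
        rows.append({"group_a": a, "group_b": b, "n_a": per_group[a].size,
                     "n_b": per_group[b].size, "u": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p"].to_numpy())
    return out
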