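"""Three-way SNP partition around an a-priori gene set.

Given gene intervals flagged as members of a gene set (e.g. human homologs
of genes implicated by model-organism experiments) and a flanking buffer
width, every SNP on the panel is assigned exactly one label:

``coding``
    position inside any gene-set gene's ``[start, stop]`` interval;
``buffer``
    otherwise within ``buffer_kb`` kilobases of a gene-set gene's start or
    stop;
``rest``
    everything else, including SNPs inside genes that are *not* in the
    gene set.

The labels are exhaustive and mutually exclusive, which is what the
downstream variance partitioning requires.  Buffers never extend across
chromosomes and intervals are clipped at position 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import GenotypePanel

logger = logging.getLogger(__name__)

LABELS = ("coding", "buffer", "rest")


@dataclass(frozen=True)
class GeneInterval:
    """A gene as a 1-based inclusive genomic interval."""

    symbol: str
    chrom: str
    start_bp: int
    stop_bp: int
    in_geneset: bool = False

    def __post_init__(self) -> None:
        if self.start_bp > self.stop_bp:
            raise ValueError(f"gene {self.symbol}: start {self.start_bp} > stop {self.stop_bp}")


@dataclass
class SnpAssignment:
    """Exclusive per-SNP partition labels for one buffer width."""

    buffer_kb: float
    labels: np.ndarray  # array of str in LABELS, aligned with the panel
    snp_ids: np.ndarray

    @property
    def counts(self) -> dict:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}

    def indices(self, label: str) -> np.ndarray:
        if label == "all":
            return np.arange(len(self.labels))
        if label not in LABELS:
            raise ValueError(f"unknown partition label {label!r}")
        return np.nonzero(self.labels == label)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp": self.snp_ids, "label": self.labels})


def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping [start, stop] intervals (inclusive)."""
    if not intervals:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    intervals = sorted(intervals)
    starts, stops = [intervals[0][0]], [intervals[0][1]]
    for s, e in intervals[1:]:
        if s <= stops[-1] + 1:
            stops[-1] = max(stops[-1], e)
        else:
            starts.append(s)
            stops.append(e)
    return np.asarray(starts), np.asarray(stops)


def _in_intervals(pos: np.ndarray, starts: np.ndarray, stops: np.ndarray) -> np.ndarray:
    if starts.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(pos.shape, dtype=bool)
    hit[ok] = pos[ok] <= stops[idx[ok]]
    return hit


def build_partition(
    genes: Iterable[GeneInterval],
    panel: GenotypePanel,
    buffer_kb: float,
) -> SnpAssignment:
    """Assign each panel SNP to coding / buffer / rest.

    Coding takes precedence over buffer where flanks of one gene overlap
    the body of another.  Genes on chromosomes absent from the panel are
    skipped with a warning.

    Raises
    ------
    ValueError
        If the gene set is empty or ``buffer_kb`` is negative.
    """
    if buffer_kb < 0:
        raise ValueError("buffer_kb must be non-negative")
    geneset = [g for g in genes if g.in_geneset]
    if not geneset:
        raise ValueError("gene set is empty: no gene has in_geneset=True")

    panel_chroms = set(panel.snp_meta["chrom"].astype(str))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in geneset:
        chrom = str(g.chrom)
        if chrom not in panel_chroms:
            msg = f"gene {g.symbol} on chromosome {chrom} absent from panel; skipped"
            logger.warning(msg)
            warnings.warn(msg)
            continue
        by_chrom.setdefault(chrom, []).append((g.start_bp, g.stop_bp))

    flank = int(round(buffer_kb * 1000))
    labels = np.full(panel.n_snps, "rest", dtype=object)
    chroms = panel.snp_meta["chrom"].astype(str).to_numpy()
    positions = panel.snp_meta["pos"].to_numpy()
    for chrom, intervals in by_chrom.items():
        on_chrom = np.nonzero(chroms == chrom)[0]
        pos = positions[on_chrom]
        cod_s, cod_e = _merge_intervals(intervals)
        in_coding = _in_intervals(pos, cod_s, cod_e)
        labels[on_chrom[in_coding]] = "coding"
        if flank > 0:
            buffered = [(max(1, s - flank), e + flank) for s, e in intervals]
            buf_s, buf_e = _merge_intervals(buffered)
            in_buf = _in_intervals(pos, buf_s, buf_e) & ~in_coding
            labels[on_chrom[in_buf]] = "buffer"

    return SnpAssignment(
        buffer_kb=float(buffer_kb),
        labels=np.asarray(labels, dtype=object),
        snp_ids=panel.snp_ids.copy(),
    )


def read_genes(path, geneset_symbols: Sequence[str] | None = None) -> list[GeneInterval]:
    """Read a gene table (symbol, chrom, start, stop TSV) into intervals.

    ``geneset_symbols`` flags the listed symbols as gene-set members.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    flagged = set(geneset_symbols) if geneset_symbols is not None else set()
    return [
        GeneInterval(
            symbol=row.symbol,
            chrom=str(row.chrom),
            start_bp=int(row.start),
            stop_bp=int(row.stop),
            in_geneset=(row.symbol in flagged) or bool(getattr(row, "in_geneset", False)),
        )
        for row in df.itertuples(index=False)
    ]


def write_genes(genes: Iterable[GeneInterval], path) -> None:
    genes = list(genes)
    pd.DataFrame(
        {
            "symbol": [g.symbol for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start_bp for g in genes],
            "stop": [g.stop_bp for g in genes],
            "in_geneset": [int(g.in_geneset) for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)
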