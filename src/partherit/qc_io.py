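"""File formats and marker quality control.

Readers/writers for PLINK 1 BED/BIM/FAM (SNP-major, 2-bit codes), the
GCTA binary GRM triple, and delimited phenotype/covariate tables, plus
the marker QC filters used before heritability analysis: per-sample call
rate, minor allele frequency, Hardy–Weinberg exact test, and per-SNP
missingness.

Dosages count copies of the A1 allele; PLINK's 2-bit codes map as
``00 -> 2 (hom A1)``, ``01 -> missing``, ``10 -> 1 (het)``, ``11 -> 0``.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyPanelError, FormatError
from .panel import GenotypePanel

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage (count of A1); code 1 is the missing sentinel
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class QcThresholds:
    """Marker QC thresholds.

    Defaults follow the common biobank pipeline: per-sample call rate
    >= 0.99, MAF > 0.01, HWE exact p > 1e-4, per-SNP missingness < 0.10.
    """

    min_maf: float = 0.01
    min_hwe_p: float = 1e-4
    max_snp_missing: float = 0.10
    min_sample_callrate: float = 0.99

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_hwe_p", "max_snp_missing", "min_sample_callrate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


# ----------------------------------------------------------------------
# PLINK BED/BIM/FAM

def read_plink(prefix) -> GenotypePanel:
    """Read a PLINK 1 fileset (``prefix`` + .bed/.bim/.fam)."""
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(
            f"{prefix}.bed: {len(raw)} bytes, expected {expected} "
            f"for {n} samples x {m} SNPs"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)
    meta = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypePanel(dosages=dosages, snp_meta=meta, sample_ids=fam["iid"].tolist())


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a PLINK 1 fileset; round-trips exactly through :func:`read_plink`."""
    prefix = str(prefix)
    n, m = panel.n_samples, panel.n_snps
    x = panel.dosages
    codes = np.full((m, n), 0b11, dtype=np.uint8)
    xt = x.T
    codes[xt == 2] = 0b00
    codes[xt == 1] = 0b10
    codes[np.isnan(xt)] = 0b01
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    body = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        body |= padded[:, shift::4] << (2 * shift)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(body.tobytes())
    meta = panel.snp_meta
    bim = pd.DataFrame(
        {"chrom": meta["chrom"], "snp": meta["snp"], "cm": 0,
         "pos": meta["pos"], "a1": meta["a1"], "a2": meta["a2"]}
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": panel.sample_ids, "iid": panel.sample_ids,
         "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
# GCTA binary GRM

def write_grm(grm, prefix) -> None:
    """Write a GRM as the GCTA binary triple (.grm.bin/.grm.N.bin/.grm.id)."""
    prefix = str(prefix)
    a = np.asarray(grm.matrix)
    n = a.shape[0]
    tri = a[np.tril_indices(n)]
    tri.astype("<f4").tofile(prefix + ".grm.bin")
    np.full(tri.shape, grm.m_snps, dtype="<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm(prefix):
    """Read a GCTA binary GRM triple written by :func:`write_grm`."""
    from .relatedness import GRM

    prefix = str(prefix)
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    n_tri = n * (n + 1) // 2
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if tri.size != n_tri:
        raise FormatError(
            f"{prefix}.grm.bin holds {tri.size} values, expected {n_tri} for {n} ids"
        )
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    if counts.size != n_tri:
        raise FormatError(f"{prefix}.grm.N.bin holds {counts.size} values, expected {n_tri}")
    a = np.zeros((n, n))
    a[np.tril_indices(n)] = tri
    a = a + np.tril(a, -1).T
    return GRM(matrix=a, sample_ids=ids, m_snps=int(round(float(counts[0]))))


# ----------------------------------------------------------------------
# phenotype / covariate tables

def write_pheno(sample_ids, values, path, name: str = "pheno") -> None:
    pd.DataFrame({"FID": sample_ids, "IID": sample_ids, name: values}).to_csv(
        path, sep="\t", index=False
    )


def read_pheno(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    if list(df.columns[:2]) != ["FID", "IID"]:
        raise FormatError(f"{path}: first two columns must be FID, IID")
    return df


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test on genotype counts.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts whose hypergeometric-class probability does not
    exceed that of the observed table.  Monomorphic sites return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero: HWE test undefined")
    # work with the rarer allele
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0
    # possible het counts share the parity of the rare-allele count
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_min, het_max + 1, 2)
    # log P(het) up to a constant: 2^het / (hom_r! het! hom_c!)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hom_r + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n_Aa)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(x)


# ----------------------------------------------------------------------
# QC filter

def qc_filter(panel: GenotypePanel, thr: QcThresholds = QcThresholds()):
    """Apply sample call-rate then per-SNP MAF / HWE / missingness filters.

    Samples below ``min_sample_callrate`` are dropped first; SNP
    statistics are then recomputed on the remaining samples.  A SNP
    failing several criteria is counted once, under the first criterion
    in the order MAF, HWE, missingness.

    Returns ``(filtered_panel, report)`` where the report counts removals
    per criterion.

    Raises
    ------
    EmptyPanelError
        If no SNP survives.
    """
    if panel.n_snps == 0 or panel.n_samples == 0:
        raise EmptyPanelError("input panel is empty")

    keep_samples = panel.sample_callrate() >= thr.min_sample_callrate
    n_samples_removed = int(np.sum(~keep_samples))
    work = panel.subset_samples(keep_samples) if n_samples_removed else panel

    maf = work.maf()
    miss = work.missing_rate()
    hwe_p = np.ones(work.n_snps)
    x = work.dosages
    for j in range(work.n_snps):
        col = x[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p[j] = 1.0
            continue
        hwe_p[j] = hwe_exact_test(
            int(np.sum(col == 2)), int(np.sum(col == 1)), int(np.sum(col == 0))
        )

    fail_maf = ~(maf > thr.min_maf)
    fail_hwe = ~(hwe_p > thr.min_hwe_p)
    fail_miss = ~(miss < thr.max_snp_missing)
    maf_removed = fail_maf
    hwe_removed = fail_hwe & ~fail_maf
    miss_removed = fail_miss & ~fail_maf & ~fail_hwe
    keep_snps = ~(fail_maf | fail_hwe | fail_miss)

    report = {
        "samples_removed": n_samples_removed,
        "maf_removed": int(maf_removed.sum()),
        "hwe_removed": int(hwe_removed.sum()),
        "missing_removed": int(miss_removed.sum()),
        "snps_kept": int(keep_snps.sum()),
        "samples_kept": work.n_samples,
    }
    if report["snps_kept"] == 0:
        raise EmptyPanelError("QC removed every SNP")
    return work.subset_snps(keep_snps), report
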