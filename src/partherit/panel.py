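"""In-memory genotype container.

A :class:`GenotypePanel` holds a sample-by-SNP additive dosage matrix
(counts of the A1 allele, ``NaN`` for missing calls) together with SNP
metadata and sample identifiers.  All downstream stages — QC, relatedness,
variance-component estimation, association and scoring — consume this one
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: required columns of ``snp_meta``
SNP_META_COLUMNS = ("snp", "chrom", "pos", "a1", "a2")


@dataclass
class GenotypePanel:
    """Dosage matrix plus marker and sample metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array; entries in ``{0, 1, 2}`` count
        copies of the A1 allele, ``NaN`` marks a missing call.
    snp_meta
        Data frame with columns ``snp, chrom, pos, a1, a2``.  Positions are
        1-based and must be strictly increasing within each chromosome;
        SNP ids must be unique.
    sample_ids
        One identifier per row of ``dosages``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ConfigurationError("dosages must be a 2-D array")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        missing_cols = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise ConfigurationError(f"snp_meta lacks columns {sorted(missing_cols)}")
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise ConfigurationError(
                f"snp_meta has {len(self.snp_meta)} rows for "
                f"{self.dosages.shape[1]} dosage columns"
            )
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ConfigurationError("sample_ids length does not match dosage rows")
        if self.snp_meta["snp"].duplicated().any():
            raise ConfigurationError("SNP ids are not unique")
        for _, sub in self.snp_meta.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError(
                    "positions not strictly increasing within a chromosome"
                )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp"].to_numpy()

    def allele_freq(self) -> np.ndarray:
        """Sample frequency of the A1 allele per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_callrate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    # ------------------------------------------------------------------
    def imputed(self, snp_indices=None) -> np.ndarray:
        """Dosages with missing calls replaced by the SNP mean (2p)."""
        x = self.dosages if snp_indices is None else self.dosages[:, snp_indices]
        x = x.copy()
        col_mean = np.nanmean(x, axis=0)
        nan_rows, nan_cols = np.nonzero(np.isnan(x))
        x[nan_rows, nan_cols] = col_mean[nan_cols]
        return x

    def standardized(self, snp_indices=None) -> np.ndarray:
        """Mean-imputed dosages centred at 2p and scaled by sqrt(2p(1-p)).

        Monomorphic SNPs (zero variance under HWE scaling) are returned as
        all-zero columns rather than dividing by zero.
        """
        x = self.imputed(snp_indices)
        p = x.mean(axis=0) / 2.0
        scale = np.sqrt(2.0 * p * (1.0 - p))
        z = x - 2.0 * p
        nz = scale > 0
        z[:, nz] /= scale[nz]
        z[:, ~nz] = 0.0
        return z

    # ------------------------------------------------------------------
    def subset_snps(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.nonzero(indices)[0]
        return GenotypePanel(
            dosages=self.dosages[:, indices],
            snp_meta=self.snp_meta.iloc[indices].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.nonzero(indices)[0]
        return GenotypePanel(
            dosages=self.dosages[indices, :],
            snp_meta=self.snp_meta.copy(),
            sample_ids=[self.sample_ids[i] for i in indices],
        )
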