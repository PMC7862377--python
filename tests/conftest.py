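import numpy as np
import pandas as pd
import pytest

from partherit import (
    GenotypePanel,
    SimConfig,
    build_partition,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-sample, 1200-SNP cohort with the default architecture."""
    return simulate_cohort(SimConfig(n_samples=300, n_snps=1200, seed=1))


@pytest.fixture(scope="session")
def small_assignment(small_cohort):
    cfg_buffer = 10.0
    return build_partition(small_cohort.genes, small_cohort.panel, cfg_buffer)


def make_panel(dosages, positions=None, chroms=None):
    """Hand-build a panel from a dosage matrix for unit tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    if chroms is None:
        chroms = ["1"] * m
    meta = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": chroms,
            "pos": positions,
            "a1": "A",
            "a2": "C",
        }
    )
    return GenotypePanel(
        dosages=dosages, snp_meta=meta, sample_ids=[f"i{i}" for i in range(n)]
    )
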