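"""PLINK codec, GRM binary dialect, HWE exact test, and the QC filter."""

import math
from fractions import Fraction

import numpy as np
import pytest

from partherit import (
    GRM,
    QcThresholds,
    SimConfig,
    compute_grm,
    hwe_exact_test,
    qc_filter,
    read_grm,
    read_plink,
    simulate_genotypes,
    write_grm,
    write_plink,
)
from partherit.errors import EmptyPanelError, FormatError
from conftest import make_panel


# ----------------------------------------------------------------------
# PLINK bed

def test_bed_decoding_matches_hand_decoded_bytes(tmp_path):
    # 3 samples x 2 SNPs.  Dosages count A1 copies:
    #   SNP0: (0, 1, 2)       -> codes 11, 10, 00 -> byte 0b00_00_10_11 = 0x0B
    #   SNP1: (miss, 2, 0)    -> codes 01, 00, 11 -> byte 0b00_11_00_01 = 0x31
    (tmp_path / "x.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0x0B, 0x31]))
    (tmp_path / "x.bim").write_text("1\ts0\t0\t100\tA\tC\n1\ts1\t0\t200\tA\tC\n")
    (tmp_path / "x.fam").write_text("\n".join(f"f{i} i{i} 0 0 0 -9" for i in range(3)))
    panel = read_plink(tmp_path / "x")
    expected = np.array([[0, np.nan], [1, 2], [2, 0]], dtype=float)
    assert np.array_equal(panel.dosages, expected, equal_nan=True)
    assert list(panel.snp_meta["pos"]) == [100, 200]


def test_plink_round_trip_is_byte_identical(tmp_path):
    cfg = SimConfig(n_samples=40, n_snps=60, n_genes=6, n_geneset_genes=3, seed=8)
    panel = simulate_genotypes(cfg)
    panel.dosages[3, 7] = np.nan
    write_plink(panel, tmp_path / "a")
    back = read_plink(tmp_path / "a")
    assert np.array_equal(panel.dosages, back.dosages, equal_nan=True)
    assert list(back.snp_meta["snp"]) == list(panel.snp_meta["snp"])
    write_plink(back, tmp_path / "b")
    assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()


def test_bed_errors(tmp_path):
    (tmp_path / "x.bim").write_text("1\ts0\t0\t100\tA\tC\n")
    (tmp_path / "x.fam").write_text("\n".join(f"f{i} i{i} 0 0 0 -9" for i in range(5)))
    (tmp_path / "x.bed").write_bytes(bytes([0x00, 0x1B, 0x01, 0x0B]))
    with pytest.raises(FormatError, match="magic"):
        read_plink(tmp_path / "x")
    # right magic, but sized for 4 samples while fam lists 5
    (tmp_path / "x.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]) + b"\x00" * 1)
    with pytest.raises(FormatError, match="expected"):
        read_plink(tmp_path / "x")


# ----------------------------------------------------------------------
# GCTA GRM binary

def test_grm_round_trip_and_length(tmp_path):
    g = GRM(matrix=np.array([[1.0, 0.25], [0.25, 0.9]]), sample_ids=["a", "b"], m_snps=7)
    write_grm(g, tmp_path / "g")
    assert (tmp_path / "g.grm.bin").stat().st_size == 3 * 4  # n(n+1)/2 float32
    back = read_grm(tmp_path / "g")
    assert np.array_equal(back.matrix, g.matrix.astype(np.float32).astype(float))
    assert back.sample_ids == ["a", "b"] and back.m_snps == 7


def test_grm_three_samples_file_length(tmp_path):
    g = GRM(matrix=np.eye(3), sample_ids=list("abc"), m_snps=5)
    write_grm(g, tmp_path / "g")
    assert (tmp_path / "g.grm.bin").stat().st_size == 6 * 4


def test_truncated_grm_raises(tmp_path):
    g = GRM(matrix=np.eye(3), sample_ids=list("abc"), m_snps=5)
    write_grm(g, tmp_path / "g")
    raw = (tmp_path / "g.grm.bin").read_bytes()
    (tmp_path / "g.grm.bin").write_bytes(raw[:-4])
    with pytest.raises(FormatError):
        read_grm(tmp_path / "g")


# ----------------------------------------------------------------------
# HWE exact test

def _hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration over all heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0
    denom = Fraction(math.factorial(2 * n),
                     math.factorial(n_rare) * math.factorial(2 * n - n_rare))
    probs = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        ways = Fraction(math.factorial(n),
                        math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c))
        probs[h] = ways * Fraction(2) ** h / denom
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


@pytest.mark.parametrize(
    "counts,expected",
    [((50, 0, 50), None), ((25, 50, 25), 1.0), ((0, 0, 10), 1.0), ((10, 0, 0), 1.0)],
)
def test_hwe_reference_points(counts, expected):
    p = hwe_exact_test(*counts)
    if expected is None:
        assert p < 1e-10  # maximal disequilibrium
    else:
        assert p == pytest.approx(expected)


def test_hwe_matches_enumeration_oracle():
    rng = np.random.default_rng(0)
    for _ in range(60):
        n = int(rng.integers(2, 200))
        n_AA = int(rng.integers(0, n + 1))
        n_Aa = int(rng.integers(0, n - n_AA + 1))
        n_aa = n - n_AA - n_Aa
        assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
            _hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-12
        )


def test_hwe_rejects_empty_input():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


# ----------------------------------------------------------------------
# QC filter

def test_qc_removes_low_maf_snp():
    rng = np.random.default_rng(1)
    common = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
    rare = np.zeros((200, 1))
    rare[:2, 0] = 1.0  # MAF 0.005
    panel = make_panel(np.hstack([common, rare]))
    filtered, report = qc_filter(panel, QcThresholds(min_maf=0.01))
    assert report["maf_removed"] == 1 and filtered.n_snps == 1


def test_qc_all_pass_is_identity(small_cohort):
    panel = small_cohort.panel
    filtered, report = qc_filter(panel)
    assert filtered.n_snps == panel.n_snps
    assert report["maf_removed"] == report["hwe_removed"] == report["missing_removed"] == 0
    assert np.array_equal(filtered.dosages, panel.dosages)


def test_snp_failing_maf_and_hwe_counted_under_maf():
    # one SNP: 2 het carriers in 200 -> MAF 0.005; plus an extreme-HWE SNP
    rng = np.random.default_rng(7)
    x = np.zeros((200, 3))
    x[:2, 0] = 1.0
    x[:100, 1] = 2.0  # (100 hom, 0 het, 100 hom): fails HWE, MAF 0.5
    x[:, 2] = rng.binomial(2, 0.4, size=200)  # survives
    panel = make_panel(x)
    _, report = qc_filter(panel, QcThresholds())
    assert report["maf_removed"] == 1
    assert report["hwe_removed"] == 1


def test_qc_sample_callrate_filter_runs_first():
    rng = np.random.default_rng(3)
    x = rng.binomial(2, 0.4, size=(50, 20)).astype(float)
    x[0, :10] = np.nan  # callrate 0.5 for sample 0
    panel = make_panel(x)
    filtered, report = qc_filter(panel, QcThresholds(min_sample_callrate=0.9))
    assert report["samples_removed"] == 1
    assert filtered.n_samples == 49
    assert not np.isnan(filtered.dosages).any()


def test_qc_filter_idempotent():
    rng = np.random.default_rng(4)
    x = rng.binomial(2, rng.uniform(0.005, 0.5, size=30), size=(150, 30)).astype(float)
    mask = rng.random(x.shape) < 0.03
    x[mask] = np.nan
    once, _ = qc_filter(make_panel(x))
    twice, report = qc_filter(once)
    assert np.array_equal(once.dosages, twice.dosages, equal_nan=True)
    assert report["maf_removed"] == report["hwe_removed"] == report["missing_removed"] == 0


def test_qc_raises_when_everything_fails():
    x = np.zeros((100, 2))  # monomorphic, MAF 0
    with pytest.raises(EmptyPanelError):
        qc_filter(make_panel(x), QcThresholds())


def test_qc_thresholds_validated():
    with pytest.raises(ValueError):
        QcThresholds(min_maf=1.5)
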