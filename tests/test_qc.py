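"""Genotype QC: exact HWE test vs an enumeration oracle, filters, iteration."""

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pandas as pd
import pytest

from wssgblup import (GenotypeMatrix, QCThresholds, hwe_exact_test,
                      iterative_qc, minor_allele_frequency)
from wssgblup.qc import apply_sample_filters, apply_snp_filters


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-fraction enumeration of the conditional heterozygote distribution.

    P(n_Aa | allele counts) = 2^het * n! / (AA! Aa! aa!) normalized over all
    heterozygote counts with the right parity; the p-value sums outcomes no
    more probable than the observed one.  All arithmetic in Fractions.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    probs = {}
    for het in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het] = Fraction(2**het * factorial(n),
                              factorial(het) * factorial(hom_r) * factorial(hom_c))
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


def make_geno(dosages, chroms=None, bp=None, quality=None, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        sample_ids=ids or [f"s{i}" for i in range(n)],
        snp_map=pd.DataFrame({
            "chrom": chroms if chroms is not None else np.ones(m, dtype=int),
            "snp_id": [f"snp{j}" for j in range(m)],
            "cm": np.arange(m, dtype=float),
            "bp": bp if bp is not None else (np.arange(m) + 1) * 1000,
        }),
        dosages=dosages,
        quality=quality,
    )


class TestMAF:
    @pytest.mark.parametrize("col,expected", [
        ([0, 0, 0, 0], 0.0),
        ([2, 2, 2, 2], 0.0),
        ([0, 1, 2, 1], 0.5),
        ([0, 0, 0, 1], 0.125),
    ])
    def test_values(self, col, expected):
        assert minor_allele_frequency(np.array(col, dtype=float)) == expected

    def test_missing_ignored(self):
        assert minor_allele_frequency(np.array([0, 1, np.nan, 1])) == \
            pytest.approx(2 / 6)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            minor_allele_frequency(np.array([np.nan, np.nan]))


class TestHWE:
    def test_monomorphic_p_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    @pytest.mark.parametrize("counts", [
        (25, 50, 25), (50, 0, 50), (3, 5, 2), (0, 10, 0), (40, 20, 40),
        (1, 1, 1), (12, 2, 0), (7, 23, 11),
    ])
    def test_matches_enumeration_oracle(self, counts):
        got = hwe_exact_test(*counts)
        want = hwe_enumeration_oracle(*counts)
        assert got == pytest.approx(want, rel=1e-10)

    def test_extreme_het_deficit_below_threshold(self):
        assert hwe_exact_test(50, 0, 50) < 1e-5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestSNPFilters:
    def test_maf_boundary_kept(self):
        # 100 samples, 4 alt alleles -> MAF exactly 0.02: the rule is strict '<'
        col = np.zeros(100)
        col[:4] = 1.0
        other = np.tile([0.0, 1.0, 2.0, 1.0], 25)
        keep, tab = apply_snp_filters(make_geno(np.column_stack([col, other])),
                                      QCThresholds())
        assert keep[0] and keep[1]
        assert len(tab) == 0

    def test_maf_below_boundary_removed(self):
        col = np.zeros(100)
        col[:3] = 1.0  # MAF 0.015
        other = np.tile([0.0, 1.0, 2.0, 1.0], 25)
        keep, tab = apply_snp_filters(make_geno(np.column_stack([col, other])),
                                      QCThresholds())
        assert not keep[0]
        assert tab.iloc[0]["rule"] == "maf"

    def test_same_position_removes_all_members(self):
        D = np.tile([0.0, 1.0, 2.0, 1.0], (3, 1)).T.repeat(25, axis=0)[:4]
        D = np.tile([[0.0, 1.0, 1.0], [1.0, 0.0, 2.0],
                     [2.0, 1.0, 0.0], [1.0, 2.0, 1.0]], (25, 1))
        geno = make_geno(D, bp=[500000, 500000, 700000])
        keep, tab = apply_snp_filters(geno, QCThresholds())
        assert list(keep) == [False, False, True]
        assert set(tab["rule"]) == {"same_position"}

    def test_non_autosomal_removed_first(self):
        D = np.tile([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0], [1.0, 1.0]], (25, 1))
        geno = make_geno(D, chroms=["X", "1"])
        keep, tab = apply_snp_filters(geno, QCThresholds())
        assert list(keep) == [False, True]
        assert tab.iloc[0]["rule"] == "non_autosomal"

    def test_call_rate_rule(self):
        col = np.array([np.nan] * 6 + [0.0, 1.0, 2.0, 1.0] * 23 + [1.0, 1.0])
        other = np.tile([0.0, 1.0, 2.0, 1.0], 25)
        keep, tab = apply_snp_filters(make_geno(np.column_stack([col, other])),
                                      QCThresholds())
        assert not keep[0]  # 94/100 called
        assert tab.iloc[0]["rule"] == "call_rate"

    def test_quality_rule(self):
        D = np.tile([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0], [1.0, 1.0]], (25, 1))
        keep, tab = apply_snp_filters(make_geno(D, quality=[0.10, 0.9]),
                                      QCThresholds())
        assert list(keep) == [False, True]
        assert tab.iloc[0]["rule"] == "quality"


class TestSampleFilters:
    def test_call_rate_boundary(self):
        D = np.tile([0.0, 1.0, 2.0, 1.0, 0.0, 1.0, 2.0, 1.0, 0.0, 1.0], (3, 1))
        D[0, :1] = np.nan  # 90% called -> kept
        D[1, :2] = np.nan  # 80% called -> removed
        keep, tab = apply_sample_filters(make_geno(D), QCThresholds())
        assert list(keep) == [True, False, True]
        assert tab.iloc[0]["rule"] == "sample_call_rate"

    def test_duplicates_keep_smallest_id(self):
        row = [0.0, 1.0, 2.0, 1.0]
        D = np.array([row, row, [1.0, 1.0, 0.0, 2.0]])
        keep, tab = apply_sample_filters(
            make_geno(D, ids=["zeta", "alpha", "beta"]), QCThresholds())
        assert list(keep) == [False, True, True]
        assert tab.iloc[0]["id"] == "zeta"

    def test_clean_matrix_no_removals(self):
        rng = np.random.default_rng(0)
        D = rng.integers(0, 3, size=(10, 8)).astype(float)
        keep, tab = apply_sample_filters(make_geno(D), QCThresholds())
        assert keep.all() and len(tab) == 0


def cascade_fixture():
    """5 samples x 3 SNPs where QC needs exactly two productive rounds.

    Sample s4 (call rate 1/3) falls in round 1; only once it is gone does
    SNP A's call frequency drop from 4/5 (passing) to 3/4 (failing), so A
    is removed in round 2 and nowhere else.
    """
    D = np.array([
        [np.nan, 0.0, 1.0],   # s0
        [1.0, 1.0, 2.0],      # s1
        [0.0, 2.0, 0.0],      # s2
        [1.0, 1.0, 1.0],      # s3
        [1.0, np.nan, np.nan],  # s4: low call rate
    ])
    thresholds = QCThresholds(snp_call_rate_min=0.79, sample_call_rate_min=0.5)
    return make_geno(D), thresholds


class TestIterativeQC:
    def test_two_round_cascade(self):
        geno, thresholds = cascade_fixture()
        clean, report = iterative_qc(geno, thresholds)
        assert report.n_productive_rounds == 2
        frame = report.to_frame()
        # round 1 removes only the bad sample
        r1 = frame[frame["round"] == 1]
        assert list(r1["id"]) == ["s4"] and list(r1["rule"]) == ["sample_call_rate"]
        # round 2 removes only SNP A, by the call-frequency rule
        r2 = frame[frame["round"] == 2]
        assert list(r2["id"]) == ["snp0"] and list(r2["rule"]) == ["call_rate"]
        assert clean.m == 2 and clean.n == 4
        # re-running removes nothing
        _, report2 = iterative_qc(clean, thresholds)
        assert report2.n_productive_rounds == 0

    def test_clean_matrix_single_round(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.3, 0.7, size=12)
        D = rng.binomial(2, p, size=(30, 12)).astype(float)
        geno = make_geno(D)
        clean, report = iterative_qc(geno, QCThresholds())
        assert report.n_rounds == 1
        assert report.n_productive_rounds == 0
        assert clean.m == 12 and clean.n == 30

    def test_idempotence_and_post_hoc_rules(self, small_dataset):
        _, _, geno, _, _, _ = small_dataset
        rng = np.random.default_rng(2)
        D = geno.dosages.copy()
        mask = rng.random(D.shape) < 0.02
        D[mask] = np.nan
        noisy = GenotypeMatrix(geno.sample_ids, geno.snp_map, D)
        clean, report = iterative_qc(noisy, QCThresholds())
        again, report2 = iterative_qc(clean, QCThresholds())
        assert report2.n_productive_rounds == 0
        assert again.m == clean.m and again.n == clean.n
        # every surviving SNP satisfies every SNP rule simultaneously
        keep, tab = apply_snp_filters(clean, QCThresholds())
        assert keep.all()
        # every removal is logged exactly once
        frame = report.to_frame()
        assert not frame.duplicated(subset=["entity", "id"]).any()
        n_snp_removed = (frame["entity"] == "snp").sum()
        assert n_snp_removed == noisy.m - clean.m
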