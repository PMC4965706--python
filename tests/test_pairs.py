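"""Pair statistic: worked values, 8-combo oracle, symmetry, partitioning."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldgwas import (
    InputError,
    ScanPartition,
    even_partitions,
    merge_partitions,
    multi_scan,
    pair_ld,
    simulate_matrix,
    single_snp_ld,
    sort_pairs,
    SimConfig,
    worked_example_fixture,
)

from conftest import oracle_pair, oracle_pair_value, random_pair_instance


class TestPairLD:
    def test_worked_example_values(self, toy):
        matrix, pheno = toy
        res = pair_ld(matrix.snp_alleles(0), matrix.snp_alleles(1), pheno)
        assert res.best_combo == (1, 1, 1)
        assert res.d_all[0, 0, 0] == pytest.approx(0.125, abs=1e-15)
        assert res.r == pytest.approx(0.125 / np.sqrt(0.25 * 0.75 * 0.25), abs=1e-12)
        assert res.r2 == pytest.approx(1 / 3, abs=1e-12)
        assert res.n_obs == 8

    def test_perfect_combination(self):
        # haplotypes carrying A1 and B1 are exactly the case haplotypes
        a = np.array([1, 1, 1, 1, 0, 0, 1, 0], dtype=np.int8)
        b = np.array([1, 1, 1, 1, 1, 1, 0, 0], dtype=np.int8)
        codes = np.array([1, 1, 0, 0], dtype=np.int8)
        res = pair_ld(a, b, codes)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.best_combo == (1, 1, 1)

    def test_complement_phenotype_flips_sign(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b, codes = random_pair_instance(rng)
            res = pair_ld(a, b, codes)
            if res.degenerate:
                continue
            for i in range(2):
                for j in range(2):
                    assert res.d_all[i, j, 0] == pytest.approx(
                        -res.d_all[i, j, 1], abs=1e-12
                    )

    def test_counts_sum_to_n_obs(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a, b, codes = random_pair_instance(rng)
            res = pair_ld(a, b, codes)
            if res.counts is not None:
                assert res.counts.sum() == res.n_obs

    def test_zero_observations_degenerate(self):
        a = np.full(8, -1, dtype=np.int8)
        b = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=np.int8)
        res = pair_ld(a, b, np.array([1, 1, 0, 0]))
        assert res.degenerate and res.n_obs == 0

    def test_monomorphic_partner_reduces_to_single(self):
        """With B monomorphic, the non-degenerate combos carry exactly the
        single-SNP information of A."""
        rng = np.random.default_rng(13)
        checked = 0
        for _ in range(300):
            a, _, codes = random_pair_instance(rng)
            b = np.where(a >= 0, 1, a).astype(np.int8)  # all B1 where defined
            pair = pair_ld(a, b, codes)
            single = single_snp_ld(a, codes)
            assert pair.degenerate == single.degenerate
            if not pair.degenerate:
                assert pair.r2 == pytest.approx(single.r2, abs=1e-12)
                checked += 1
        assert checked > 100


class TestPairOracle:
    def test_matches_bruteforce_max_on_random_instances(self):
        rng = np.random.default_rng(20240902)
        checked = 0
        for _ in range(1200):
            a, b, codes = random_pair_instance(rng)
            res = pair_ld(a, b, codes)
            expected_r, expected_combo = oracle_pair(a, b, codes)
            if expected_r is None:
                assert res.degenerate
            else:
                assert res.r == pytest.approx(expected_r, abs=1e-12)
                if res.best_combo != expected_combo:
                    # an exact tie resolved differently at the last float
                    # bit: the chosen combo must still attain the maximum
                    tied = oracle_pair_value(a, b, codes, res.best_combo)
                    assert tied == pytest.approx(expected_r, abs=1e-12)
                checked += 1
        assert checked > 400

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_and_relabel_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b, codes = random_pair_instance(rng)
        base = pair_ld(a, b, codes)

        swapped = pair_ld(b, a, codes)
        assert swapped.r2 == base.r2  # exact: same 8 ratios, permuted

        flip = lambda v: np.where(v >= 0, 1 - v, v).astype(np.int8)
        assert pair_ld(flip(a), b, codes).r2 == base.r2
        assert pair_ld(a, flip(b), codes).r2 == base.r2
        flipped_codes = np.where(codes >= 0, 1 - codes, codes).astype(np.int8)
        assert pair_ld(a, b, flipped_codes).r2 == base.r2


class TestPhaseAmbiguity:
    def _instance(self):
        # s1 doubly het unphased, s2 doubly het phased, s3/s4 homozygous
        a = np.array([0, 1, 0, 1, 1, 1, 0, 0], dtype=np.int8)
        b = np.array([1, 0, 0, 1, 1, 1, 0, 0], dtype=np.int8)
        codes = np.array([1, 1, 0, 0], dtype=np.int8)
        phased_a = np.array([False, True, True, True])
        phased_b = np.array([True, True, True, True])
        return a, b, codes, phased_a, phased_b

    def test_ambiguous_counted_by_default(self):
        a, b, codes, pa, pb = self._instance()
        res = pair_ld(a, b, codes, phased_a=pa, phased_b=pb)
        assert res.n_phase_ambiguous == 2  # both haplotypes of s1
        assert res.n_obs == 8

    def test_strict_mode_excludes_ambiguous(self):
        a, b, codes, pa, pb = self._instance()
        res = pair_ld(a, b, codes, phased_a=pa, phased_b=pb, strict_phase=True)
        assert res.n_obs == 6
        # equivalent to dropping sample 1 entirely
        drop = pair_ld(a[2:], b[2:], codes[1:])
        assert res.r2 == pytest.approx(drop.r2, abs=1e-15)

    def test_single_het_not_ambiguous(self):
        a, b, codes, pa, pb = self._instance()
        b_hom = np.where(b >= 0, 1, b).astype(np.int8)
        res = pair_ld(a, b_hom, codes, phased_a=pa, phased_b=pb)
        assert res.n_phase_ambiguous == 0


@pytest.fixture(scope="module")
def small_cohort():
    config = SimConfig(
        n_cases=30, n_controls=30, n_snps=12, seed=42, maf_range=(0.2, 0.4)
    )
    cohort = simulate_matrix(config)
    return cohort.matrix, cohort.pheno


class TestMultiScan:
    def test_pair_enumeration_count(self, small_cohort):
        matrix, pheno = small_cohort
        anchors = [0, 1, 2]
        results = multi_scan(matrix, pheno, anchors, min_r2=0.0)
        assert len(results) == 3 * (matrix.n_snps - 1)
        assert not any(r.snp_a.id == r.snp_b.id for r in results)

    def test_min_r2_one_keeps_only_perfect_pairs(self, small_cohort):
        matrix, pheno = small_cohort
        results = multi_scan(matrix, pheno, [0, 1], min_r2=1.0)
        assert all(r.r2 >= 1.0 for r in results)

    def test_invalid_partition_rejected(self, small_cohort):
        matrix, pheno = small_cohort
        with pytest.raises(InputError):
            multi_scan(matrix, pheno, [0, 1], partition=ScanPartition(0, 5, 1))
        with pytest.raises(InputError):
            ScanPartition(-1, 2, 1)
        with pytest.raises(InputError):
            ScanPartition(3, 3, 1)

    def test_call_count_matches_complexity_claim(self, small_cohort, monkeypatch):
        """A partition scan performs exactly |anchors in partition| × (L−1)
        pair computations."""
        import ldgwas.pairs as pairs_mod

        calls = {"n": 0}
        orig = pairs_mod.pair_ld

        def counting(*args, **kwargs):
            calls["n"] += 1
            return orig(*args, **kwargs)

        monkeypatch.setattr(pairs_mod, "pair_ld", counting)
        matrix, pheno = small_cohort
        anchors = [0, 3, 5, 7]
        multi_scan(matrix, pheno, anchors, partition=ScanPartition(1, 3, 1), min_r2=0.0)
        assert calls["n"] == 2 * (matrix.n_snps - 1)


class TestPartitioning:
    def _full(self, matrix, pheno, anchors):
        part = ScanPartition(0, len(anchors), 1)
        return merge_partitions(
            [(part, multi_scan(matrix, pheno, anchors, part, min_r2=0.0))]
        )

    def test_merge_identity_k1(self, small_cohort):
        matrix, pheno = small_cohort
        anchors = [0, 1, 2, 3]
        merged = self._full(matrix, pheno, anchors)
        assert len(merged) == 4 * (matrix.n_snps - 1)

    @pytest.mark.parametrize("k", [2, 3])
    def test_partition_cover_equals_monolithic(self, small_cohort, k):
        matrix, pheno = small_cohort
        anchors = [0, 2, 4, 6, 8, 10]
        mono = self._full(matrix, pheno, anchors)
        parts = [
            (p, multi_scan(matrix, pheno, anchors, p, min_r2=0.0))
            for p in even_partitions(len(anchors), k)
        ]
        merged = merge_partitions(parts)
        assert [(r.snp_a.id, r.snp_b.id, r.r2) for r in merged] == [
            (r.snp_a.id, r.snp_b.id, r.r2) for r in mono
        ]

    def test_overlapping_partitions_rejected(self):
        parts = [
            (ScanPartition(0, 3, 2), []),
            (ScanPartition(2, 5, 2), []),
        ]
        with pytest.raises(InputError, match="overlap"):
            merge_partitions(parts)

    def test_gapped_partitions_rejected(self):
        parts = [
            (ScanPartition(0, 2, 2), []),
            (ScanPartition(3, 5, 2), []),
        ]
        with pytest.raises(InputError, match="gap"):
            merge_partitions(parts)

    def test_wrong_k_total_rejected(self):
        with pytest.raises(InputError):
            merge_partitions([(ScanPartition(0, 2, 2), [])])
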