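"""Diversity indices, Weir-Cockerham theta, AMOVA and Phi_ST."""

import math

import numpy as np
import pytest

from spinypop.genotype_io import MISSING, GenotypeMatrix, HaplotypeAlignment
from spinypop.popgen_stats import (
    allelic_richness,
    amova,
    diversity_table,
    phi_st,
    smlh,
    wc_fst_pairwise,
    wc_theta,
)
from spinypop.synthetic_data import simulate_mtdna

from conftest import random_matrix


def matrix_from(calls, pops=None):
    calls = np.asarray(calls, dtype=np.int16)
    n, L = calls.shape
    ids = [f"i{k}" for k in range(n)]
    if pops is None:
        pops = {i: "x" for i in ids}
    else:
        pops = {i: p for i, p in zip(ids, pops)}
    return GenotypeMatrix(ids, [f"L{j}" for j in range(L)], calls, pops)


class TestDiversityTable:
    def test_all_heterozygous_extreme(self):
        n = 6
        m = matrix_from(np.ones((n, 4)))
        t = diversity_table(m).table
        assert t.loc["x", "Ho"] == pytest.approx(1.0)
        assert t.loc["x", "He"] == pytest.approx(0.5 * 2 * n / (2 * n - 1))
        assert t.loc["x", "FIS"] < 0

    def test_hand_computed_small_matrix(self):
        # 4 individuals, 3 loci, complete data, one population
        calls = [[0, 1, 2],
                 [1, 1, 0],
                 [2, 0, 0],
                 [1, 2, 1]]
        m = matrix_from(calls)
        t = diversity_table(m).table
        # per-locus: p = (4/8, 4/8, 3/8); Ho = (2/4, 2/4, 1/4)
        he = [2 * p * (1 - p) * 8 / 7 for p in (0.5, 0.5, 3 / 8)]
        ho = [0.5, 0.5, 0.25]
        assert t.loc["x", "He"] == pytest.approx(np.mean(he))
        assert t.loc["x", "Ho"] == pytest.approx(np.mean(ho))
        assert t.loc["x", "FIS"] == pytest.approx(1 - sum(ho) / sum(he))
        assert t.loc["x", "MLH"] == pytest.approx(np.mean([1/3, 2/3, 0, 2/3]))

    def test_size_one_population_flagged_undefined(self):
        m = matrix_from([[1, 0], [0, 1], [2, 1]], pops=["a", "a", "b"])
        t = diversity_table(m).table
        assert math.isnan(t.loc["b", "FIS"])
        assert t.loc["b", "N"] == 1


class TestSmlh:
    def test_identical_individuals_all_one(self):
        m = matrix_from(np.tile([1, 0, 1, 2], (5, 1)))
        assert smlh(m).to_numpy() == pytest.approx(np.ones(5))

    def test_population_mean_is_one_without_missing(self):
        m = random_matrix(n_ind=20, n_loci=50, missing_rate=0.0, seed=3)
        assert smlh(m).mean() == pytest.approx(1.0, abs=1e-6)

    def test_hand_example_with_missing_call(self):
        # 3 individuals x 2 loci; i2 untyped at L1
        calls = [[1, 0], [0, MISSING], [1, 1]]
        m = matrix_from(calls)
        s = smlh(m)
        # locus het: L0 -> 2/3 (i0,i2 het), L1 -> 1/2 among the 2 typed
        assert s["i0"] == pytest.approx((1 / 2) / ((2 / 3 + 1 / 2) / 2))
        assert s["i1"] == pytest.approx(0.0 / (2 / 3))
        assert s["i2"] == pytest.approx(1.0 / ((2 / 3 + 1 / 2) / 2))


class TestAllelicRichness:
    def test_monomorphic_is_exactly_one(self):
        m = matrix_from(np.full((6, 3), 2))
        ar = allelic_richness(m, g=4)
        assert ar.loc["x", "AR"] == pytest.approx(1.0)

    def test_biallelic_bounds(self):
        m = random_matrix(n_ind=15, n_loci=30, seed=8)
        ar = allelic_richness(m, g=6)
        assert 1.0 <= ar["AR"].min() and ar["AR"].max() <= 2.0

    def test_matches_subsample_enumeration(self):
        # one locus, 3 alt copies among 8; enumerate all C(8, g) subsets
        from itertools import combinations
        calls = [[2], [1], [0], [0]]  # 3 alt copies, 8 gene copies
        m = matrix_from(calls)
        g = 4
        copies = [1, 1, 1, 0, 0, 0, 0, 0]
        counts = []
        for sub in combinations(range(8), g):
            draw = [copies[i] for i in sub]
            counts.append(len(set(draw)))
        expected = np.mean(counts)
        ar = allelic_richness(m, g=g)
        assert ar.loc["x", "AR"] == pytest.approx(expected, abs=1e-12)


class TestWcTheta:
    def test_fixed_difference_is_one(self):
        calls = np.array([[0] * 5] * 4 + [[2] * 5] * 4)
        m = matrix_from(calls, pops=["a"] * 4 + ["b"] * 4)
        assert wc_theta(m) == pytest.approx(1.0)

    def test_identical_frequency_pools_near_zero(self, rng):
        p = rng.uniform(0.2, 0.8, 500)
        calls = rng.binomial(2, p, size=(100, 500)).astype(np.int16)
        m = matrix_from(calls, pops=["a"] * 50 + ["b"] * 50)
        assert abs(wc_theta(m)) < 0.01

    def test_pairwise_permutation_p_values(self, rng):
        p = rng.uniform(0.2, 0.8, 60)
        shift = np.clip(p + rng.normal(0, 0.35, 60), 0.02, 0.98)
        calls = np.vstack([
            rng.binomial(2, p, size=(15, 60)),
            rng.binomial(2, shift, size=(15, 60)),
        ]).astype(np.int16)
        m = matrix_from(calls, pops=["a"] * 15 + ["b"] * 15)
        res = wc_fst_pairwise(m, n_permutations=99, seed=1)
        assert res.fst.loc["a", "b"] > 0.02
        assert res.p_values.loc["a", "b"] <= 0.05
        assert res.fst.loc["a", "a"] == 0.0

    def test_orientation_and_order_invariance(self, rng):
        m = random_matrix(n_ind=20, n_loci=40, n_pops=2, seed=5)
        theta = wc_theta(m)
        flipped = m.calls.copy()
        flip = rng.random(40) < 0.5
        sub = flipped[:, flip]
        sub[sub != MISSING] = 2 - sub[sub != MISSING]
        flipped[:, flip] = sub
        m2 = GenotypeMatrix(m.individual_ids, m.locus_ids, flipped, m.population_of)
        assert wc_theta(m2) == pytest.approx(theta, abs=1e-12)
        perm = rng.permutation(20)
        m3 = m.subset(individuals=perm)
        assert wc_theta(m3) == pytest.approx(theta, abs=1e-12)


class TestAmova:
    def test_hand_computed_components(self):
        # 6 individuals, 1 locus, two populations.  Gene copies:
        # pop a = [0,0,0,0,0,1], pop b = [1,1,1,1,0,1]; six 0s and six 1s.
        # SS_total = (6*6 mismatching pairs)/12 = 3; SS_within = 5/6 + 5/6;
        # sigma_w = (10/6)/10 = 1/6; n' = (12 - 72/12)/1 = 6;
        # sigma_a = (8/6 - 1/6)/6 = 7/36; Phi = (7/36)/(7/36 + 1/6) = 7/13.
        calls = np.array([[0], [0], [1], [2], [2], [1]])
        m = matrix_from(calls, pops=["a", "a", "a", "b", "b", "b"])
        res = amova(m, n_permutations=99, seed=1)
        assert res.sigma2_within == pytest.approx(1 / 6)
        assert res.sigma2_among == pytest.approx(7 / 36)
        assert res.phi_st == pytest.approx(7 / 13)

    def test_random_split_of_one_population(self, rng):
        p = rng.uniform(0.2, 0.8, 200)
        calls = rng.binomial(2, p, size=(40, 200)).astype(np.int16)
        m = matrix_from(calls, pops=["a", "b"] * 20)
        res = amova(m, n_permutations=99, seed=2)
        assert abs(res.phi_st) < 0.02
        assert res.p_value > 0.05

    def test_agrees_with_wc_for_two_equal_pops(self, rng):
        p = rng.uniform(0.2, 0.8, 300)
        shift = np.clip(p + rng.normal(0, 0.25, 300), 0.02, 0.98)
        calls = np.vstack([
            rng.binomial(2, p, size=(25, 300)),
            rng.binomial(2, shift, size=(25, 300)),
        ]).astype(np.int16)
        m = matrix_from(calls, pops=["a"] * 25 + ["b"] * 25)
        assert amova(m, n_permutations=49, seed=3).phi_st == pytest.approx(
            wc_theta(m), abs=0.02)

    def test_single_population_rejected(self):
        m = matrix_from([[0], [1]], pops=["a", "a"])
        with pytest.raises(ValueError):
            amova(m)


class TestPhiSt:
    def test_same_haplotype_pool_near_zero(self, rng):
        pool = ["ACGTACGTAC", "ACGTACGTAA", "ACGTACGTCC", "ACGTTCGTAC"]
        ids = [f"s{k}" for k in range(20)]
        seqs = [pool[rng.integers(0, 4)] for _ in ids]
        aln = HaplotypeAlignment(ids, seqs,
                                 {i: ("a" if k < 10 else "b")
                                  for k, i in enumerate(ids)})
        res = phi_st(aln, n_permutations=99, seed=4)
        assert abs(res.phi_st) < 0.15
        assert res.p_value > 0.05

    def test_two_pure_clades_is_one(self):
        ids = [f"s{k}" for k in range(8)]
        seqs = ["AAAAAAAA"] * 4 + ["CCCCCCCC"] * 4
        aln = HaplotypeAlignment(ids, seqs,
                                 {i: ("a" if k < 4 else "b")
                                  for k, i in enumerate(ids)})
        assert phi_st(aln, n_permutations=49, seed=5).phi_st == pytest.approx(1.0)

    def test_matches_direct_variance_recomputation(self):
        aln = simulate_mtdna(divergence=8.0, n_per_pop=8, seq_length=300, seed=6)
        res = phi_st(aln, n_permutations=49, seed=6)
        # independent recomputation from the pairwise mismatch matrix
        seqs = np.array([list(s) for s in aln.sequences])
        n = len(aln.sequence_ids)
        d2 = np.array([[(seqs[i] != seqs[j]).sum() for j in range(n)]
                       for i in range(n)], dtype=float)
        ss_total = d2.sum() / (2 * n)
        ss_within = sum(
            d2[np.ix_(g, g)].sum() / (2 * len(g))
            for g in (range(0, 8), range(8, 16)))
        sigma_w = ss_within / (n - 2)
        sigma_a = ((ss_total - ss_within) - sigma_w) / 8
        assert res.phi_st == pytest.approx(sigma_a / (sigma_a + sigma_w), abs=1e-10)
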