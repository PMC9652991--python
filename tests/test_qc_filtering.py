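"""QC filter rules, the exact HWE test, and the ordered pipeline."""

import math
from fractions import Fraction

import numpy as np
import pytest

from spinypop.genotype_io import MISSING, GenotypeMatrix
from spinypop.qc_filtering import (
    FilterConfig,
    apply_filters,
    hamming_filter,
    hwe_exact_test,
    ld_prune,
    ld_r2,
    maf,
)
from spinypop.synthetic_data import make_qc_fixture, _hwe_exact_fraction

from conftest import random_matrix


def hwe_enumeration_oracle(naa, nab, nbb):
    """Exact rational enumeration over all heterozygote counts."""
    return float(_hwe_exact_fraction(naa, nab, nbb))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(25, 0, 0) == 1.0

    @pytest.mark.parametrize("table", [
        (0, 100, 0),   # all heterozygous, 100 minor alleles in 100 diploids
        (3, 5, 2),
        (10, 2, 10),
        (1, 1, 1),
        (0, 1, 14),
    ])
    def test_matches_enumeration(self, table):
        assert hwe_exact_test(*table) == pytest.approx(
            hwe_enumeration_oracle(*table), abs=1e-12)

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 25))
            g = rng.multinomial(n, [1 / 3] * 3)
            assert hwe_exact_test(*g) == pytest.approx(
                hwe_enumeration_oracle(*g), abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestMaf:
    def test_all_heterozygous_is_half(self):
        m = GenotypeMatrix(["a", "b"], ["L"], np.array([[1], [1]]),
                           {"a": "x", "b": "x"})
        assert maf(m, "L") == 0.5

    def test_monomorphic_is_zero(self):
        m = GenotypeMatrix(["a", "b"], ["L"], np.array([[2], [2]]),
                           {"a": "x", "b": "x"})
        assert maf(m, "L") == 0.0

    def test_missing_aware_hand_count(self):
        calls = np.array([[0], [1], [2], [MISSING]])
        m = GenotypeMatrix(list("abcd"), ["L"], calls, dict.fromkeys("abcd", "x"))
        assert maf(m, "L") == pytest.approx(3 / 6)

    def test_all_missing_rejected(self):
        m = GenotypeMatrix(["a"], ["L"], np.array([[MISSING]]), {"a": "x"})
        with pytest.raises(ValueError):
            maf(m, "L")


class TestLdR2:
    def test_self_correlation_is_one(self, small_matrix):
        assert ld_r2(small_matrix, "L3", "L3") == pytest.approx(1.0)

    def test_perturbed_duplicate_matches_hand_value(self):
        a = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1])
        b = a.copy()
        b[0] = 2
        m = GenotypeMatrix([f"i{k}" for k in range(10)], ["A", "B"],
                           np.column_stack([a, b]),
                           {f"i{k}": "x" for k in range(10)})
        expected = np.corrcoef(a, b)[0, 1] ** 2
        assert ld_r2(m, "A", "B") == pytest.approx(expected, abs=1e-12)

    def test_independent_loci_near_zero(self, rng):
        n = 500
        calls = rng.binomial(2, 0.5, size=(n, 2)).astype(np.int16)
        m = GenotypeMatrix([f"i{k}" for k in range(n)], ["A", "B"], calls,
                           {f"i{k}": "x" for k in range(n)})
        assert ld_r2(m, "A", "B") < 0.05

    def test_constant_locus_is_nan(self):
        calls = np.array([[0, 1], [0, 2], [0, 0]])
        m = GenotypeMatrix(list("abc"), ["A", "B"], calls, dict.fromkeys("abc", "x"))
        assert math.isnan(ld_r2(m, "A", "B"))


class TestLdPrune:
    def test_uncorrelated_all_retained(self, small_matrix):
        kept = ld_prune(small_matrix, FilterConfig())
        assert kept == small_matrix.locus_ids

    def test_identical_pair_drops_exactly_one(self, rng):
        base = rng.binomial(2, 0.5, size=(30, 5)).astype(np.int16)
        calls = np.column_stack([base, base[:, 2]])
        ids = [f"L{j}" for j in range(6)]
        m = GenotypeMatrix([f"i{k}" for k in range(30)], ids, calls,
                           {f"i{k}": "x" for k in range(30)})
        kept = ld_prune(m, FilterConfig())
        assert len(kept) == 5
        assert ("L2" in kept) != ("L5" in kept)


class TestHammingFilter:
    def _meta(self, seqs, rates):
        import pandas as pd
        from spinypop.genotype_io import LocusMetadata
        return LocusMetadata(pd.DataFrame({
            "locus_id": [f"L{j}" for j in range(len(seqs))],
            "tag_id": [f"T{j}" for j in range(len(seqs))],
            "position_in_tag": 5,
            "call_rate": rates,
            "repeatability": 0.99,
            "mean_depth": 10.0,
            "tag_sequence": seqs,
        }).set_index("locus_id"))

    def test_distant_tags_all_retained(self):
        meta = self._meta(["AAAA", "CCCC", "GGGG"], [1.0, 1.0, 1.0])
        assert hamming_filter(meta, 0.25) == ["L0", "L1", "L2"]

    def test_identical_tags_drop_lower_call_rate(self):
        meta = self._meta(["AAAA", "AAAA"], [0.9, 1.0])
        assert hamming_filter(meta, 0.25) == ["L1"]

    def test_all_pairs_oracle_on_planted_fixture(self):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAC", "CCCCCCCCCC", "CCCCCCCCGG",
                "GGGGTTTTAA"]
        rates = [1.0, 0.95, 0.8, 0.99, 1.0]
        kept = hamming_filter(self._meta(seqs, rates), 0.25)
        # brute force: pairs (0,1) d=0.1 -> drop 1; (2,3) d=0.2 -> drop 2
        assert kept == ["L0", "L3", "L4"]


class TestApplyFilters:
    def test_fixture_matches_brute_force_ground_truth(self):
        matrix, meta, truth = make_qc_fixture(seed=5)
        filtered, report = apply_filters(matrix, meta)
        assert filtered.locus_ids == truth["retained_loci"]
        assert filtered.individual_ids == truth["retained_individuals"]
        got = [(s[0], s[1], s[2]) for s in report.steps]
        assert got == truth["steps"]

    def test_clean_fixture_removes_nothing(self):
        matrix, meta, truth = make_qc_fixture(seed=5, plant_violations=False)
        filtered, report = apply_filters(matrix, meta)
        assert filtered.n_loci == matrix.n_loci
        assert filtered.n_individuals == matrix.n_individuals
        assert all(s[1] == 0 and s[2] == 0 for s in report.steps)

    def test_idempotent_on_fixture(self):
        matrix, meta, _ = make_qc_fixture(seed=5)
        once, _ = apply_filters(matrix, meta)
        twice, rep = apply_filters(once, meta.for_loci(once.locus_ids))
        assert twice.locus_ids == once.locus_ids
        assert twice.individual_ids == once.individual_ids

    def test_attrition_sums_to_dimensions(self):
        matrix, meta, _ = make_qc_fixture(seed=9)
        filtered, report = apply_filters(matrix, meta)
        loci_rm, ind_rm = report.total_removed()
        assert loci_rm == matrix.n_loci - filtered.n_loci
        assert ind_rm == matrix.n_individuals - filtered.n_individuals

    def test_empty_after_filtering_completes(self):
        # every locus monomorphic: pipeline must finish with a zero report
        calls = np.zeros((4, 3), dtype=np.int16)
        m = GenotypeMatrix(list("abcd"), ["L0", "L1", "L2"], calls,
                           dict.fromkeys("abcd", "x"))
        filtered, report = apply_filters(m, None)
        assert filtered.n_loci == 0
        assert report.steps[0][1] == 3

    def test_protocol_thresholds_are_defaults(self):
        c = FilterConfig()
        assert (c.min_locus_call_rate, c.min_indiv_call_rate) == (0.90, 0.80)
        assert (c.min_depth, c.min_repeatability) == (5, 0.95)
        assert (c.hamming_threshold, c.hwe_alpha) == (0.25, 1e-5)
        assert (c.ld_r2_max, c.max_locus_missing, c.min_maf) == (0.80, 0.10, 0.02)

    def test_yaml_round_trip(self, tmp_path):
        c = FilterConfig(min_maf=0.05, ld_window=30)
        path = tmp_path / "qc.yaml"
        c.to_yaml(path)
        assert FilterConfig.from_yaml(path) == c
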