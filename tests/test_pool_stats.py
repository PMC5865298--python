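import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolscan import (
    ConfigError,
    pooled_heterozygosity,
    tajima_constants,
    window_fst,
    window_tajima_d,
)
from conftest import snp as mk_snp
from oracles import (
    fst_bruteforce,
    tajima_constants_bruteforce,
    tajima_d_bruteforce,
)


def snps(pairs, make_snp=mk_snp):
    return [make_snp(100 + i, a, b) for i, (a, b) in enumerate(pairs)]


class TestPooledHeterozygosity:
    def test_symmetric_counts_reach_maximum(self, make_snp):
        assert pooled_heterozygosity(snps([(8, 8)], make_snp)) == 0.5

    def test_window_sum_formula(self, make_snp):
        # 2*30*10/40^2
        assert pooled_heterozygosity(snps([(20, 5), (10, 5)], make_snp)) == 0.375

    def test_monomorphic_window_is_zero(self, make_snp):
        assert pooled_heterozygosity(snps([(12, 0)], make_snp)) == 0.0

    def test_empty_window_undefined(self):
        assert math.isnan(pooled_heterozygosity([]))

    @settings(max_examples=100, deadline=None)
    @given(pairs=st.lists(
        st.tuples(st.integers(1, 30), st.integers(0, 30)), min_size=1, max_size=8,
    ))
    def test_label_swap_invariance_and_bounds(self, pairs):
        pairs = [(max(a, b), min(a, b)) for a, b in pairs]
        hp = pooled_heterozygosity(snps(pairs))
        swapped = pooled_heterozygosity(snps([(b, a) for a, b in pairs]))
        assert hp == pytest.approx(swapped, abs=0)
        assert 0.0 <= hp <= 0.5


class TestTajimaConstants:
    def test_smallest_sample(self):
        k = tajima_constants(2)
        assert (k.a1, k.a2, k.b1) == (1.0, 1.0, 1.0)

    def test_harmonic_sum_n4(self):
        assert tajima_constants(4).a1 == pytest.approx(11 / 6, rel=1e-15)

    @pytest.mark.parametrize("n", [3, 10, 16, 50])
    def test_all_constants_match_symbolic_summation(self, n):
        k = tajima_constants(n)
        ref = tajima_constants_bruteforce(n)
        for name, val in ref.items():
            assert getattr(k, name) == pytest.approx(val, rel=1e-12), name

    def test_rejects_n_below_two(self):
        with pytest.raises(ConfigError):
            tajima_constants(1)


class TestWindowTajimaD:
    def test_empty_window_undefined(self):
        tpi, tw, d = window_tajima_d([], 50)
        assert all(map(math.isnan, (tpi, tw, d)))

    def test_singleton_symmetric_site_classical(self, make_snp):
        # one SNP, 1/1 reads, n_eff = 2: theta_pi = theta_w = 1, D = 0
        tpi, tw, d = window_tajima_d(snps([(1, 1)], make_snp), 50, bias="none")
        assert (tpi, tw) == (1.0, 1.0)
        assert d == 0.0

    def test_rare_excess_negative_balanced_positive(self, make_snp):
        # near-fixed sites (rare variants) vs intermediate-frequency sites
        rare = snps([(14, 2)] * 12, make_snp)
        balanced = snps([(8, 8)] * 12, make_snp)
        d_rare = window_tajima_d(rare, 50)[2]
        d_bal = window_tajima_d(balanced, 50)[2]
        assert d_rare < 0 < d_bal

    def test_neff_capped_at_pool_size(self, make_snp):
        # median depth 16 but haploid pool size 4 caps n_eff
        records = snps([(10, 6)] * 5, make_snp)
        tpi_c, tw_c, _ = window_tajima_d(records, 4, neff_mode="pool_capped")
        tpi_r, tw_r, _ = window_tajima_d(records, 4, neff_mode="read_depth")
        assert tw_c != tw_r  # a1(4) vs a1(16)
        assert tpi_c != tpi_r  # ascertainment scaling depends on n_eff

    def test_min_count_one_equals_classical(self, make_snp):
        records = snps([(9, 3), (7, 5), (11, 2)], make_snp)
        assert window_tajima_d(records, 50, bias="min_count", min_count=1) == (
            window_tajima_d(records, 50, bias="none")
        )

    @pytest.mark.parametrize("bias", ["none", "min_count"])
    @settings(max_examples=150, deadline=None)
    @given(pairs=st.lists(
        st.tuples(st.integers(1, 11), st.integers(1, 6)), min_size=1, max_size=6,
    ))
    def test_matches_termwise_oracle(self, bias, pairs):
        """Windows of <= 6 SNPs at depths <= 12 against brute force, 1e-12."""
        pairs = [(a, b) for a, b in pairs if a + b >= 2][:6]
        if not pairs:
            return
        got = window_tajima_d(snps(pairs), 50, bias=bias)
        want = tajima_d_bruteforce(pairs, 50, bias=bias)
        for g, w in zip(got, want):
            if math.isnan(w):
                assert math.isnan(g)
            else:
                assert g == pytest.approx(w, rel=1e-12)


class TestWindowFst:
    def test_identical_frequencies_zero(self, make_snp):
        a = snps([(8, 2), (5, 5)], make_snp)
        assert window_fst(a, a) == 0.0

    def test_fixed_difference_is_one(self, make_snp):
        a = snps([(10, 0)], make_snp)
        b = snps([(0, 10)], make_snp)
        assert window_fst(a, b) == 1.0

    def test_hand_computed_example(self, make_snp):
        # p1 = 0.8, p2 = 0.4 -> F_st = 1/6
        a = snps([(8, 2)], make_snp)
        b = snps([(4, 6)], make_snp)
        assert window_fst(a, b) == pytest.approx(1 / 6, rel=1e-12)

    def test_all_fixed_same_direction_undefined(self, make_snp):
        a = snps([(10, 0), (7, 0)], make_snp)
        assert math.isnan(window_fst(a, a))

    def test_unknown_scheme_rejected(self, make_snp):
        with pytest.raises(ConfigError):
            window_fst(snps([(5, 5)], make_snp), snps([(5, 5)], make_snp), "foo")

    @pytest.mark.parametrize("scheme", ["ratio_of_sums", "mean_of_ratios"])
    @settings(max_examples=150, deadline=None)
    @given(data=st.lists(
        st.tuples(st.integers(0, 8), st.integers(0, 8),
                  st.integers(0, 8), st.integers(0, 8)),
        min_size=1, max_size=6,
    ))
    def test_symmetry_bounds_and_oracle(self, scheme, data):
        data = [(a1 + 1, b1, a2 + 1, b2) for a1, b1, a2, b2 in data]
        a = snps([(x[0], x[1]) for x in data])
        b = snps([(x[2], x[3]) for x in data])
        fab = window_fst(a, b, scheme)
        fba = window_fst(b, a, scheme)
        want = fst_bruteforce(
            [(x[0], x[1]) for x in data], [(x[2], x[3]) for x in data], scheme
        )
        if math.isnan(want):
            assert math.isnan(fab)
        else:
            assert fab == pytest.approx(want, rel=1e-12, abs=1e-15)
            assert fab == pytest.approx(fba, rel=1e-12, abs=1e-15)
            assert 0.0 <= fab <= 1.0
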