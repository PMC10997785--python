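import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heritpart.exceptions import MonomorphicSNPError, RegionTooSparseError
from heritpart.grm import (
    GRM,
    AlleleFrequencies,
    allele_frequencies,
    build_grm,
    fhat3,
    maf_subset,
    region_subset,
    relatedness_summary,
    threshold_grm,
)

from conftest import make_genotypes, make_snp_table


def naive_grm(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-pair, per-SNP double-loop evaluation of the standardised estimator.

    Independent oracle: no vectorisation shared with the implementation.
    """
    n, m = dosages.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for z in range(m):
                het = 2.0 * p[z] * (1.0 - p[z])
                if i == j:
                    s = dosages[i, z]
                    acc += (s * s - (1.0 + 2.0 * p[z]) * s + 2.0 * p[z] ** 2) / het
                else:
                    acc += ((dosages[i, z] - 2 * p[z]) * (dosages[j, z] - 2 * p[z])) / het
            out[i, j] = acc / m + (1.0 if i == j else 0.0)
    return out


class TestAlleleFrequencies:
    def test_hand_counts(self):
        g = make_genotypes(np.array([[0.0], [1.0], [2.0], [2.0]]))
        af = allele_frequencies(g)
        assert af.p[0] == pytest.approx(0.625)

    def test_all_zero_column_gives_zero(self):
        g = make_genotypes(np.zeros((3, 1)))
        assert allele_frequencies(g).p[0] == 0.0

    def test_missing_excluded_from_denominator(self):
        g = make_genotypes(np.array([[2.0], [np.nan], [0.0], [2.0]]))
        af = allele_frequencies(g)
        assert af.p[0] == pytest.approx(4.0 / 6.0)
        assert af.n_obs[0] == 3

    def test_all_missing_column_names_snp(self):
        g = make_genotypes(np.array([[np.nan], [np.nan]]))
        with pytest.raises(ValueError, match="snp0"):
            allele_frequencies(g)


class TestBuildGRM:
    def test_single_snp_off_diagonal_hand_value(self):
        # p = 0.5, s_i = 2, s_j = 0: (2-1)(0-1)/0.5 = -2
        g = make_genotypes(np.array([[2.0], [0.0]]))
        grm = build_grm(g)
        assert grm.values[0, 1] == pytest.approx(-2.0)

    def test_single_snp_diagonal_hand_value(self):
        # p = 0.5 forced via freqs; s = 1: 1 + (1 - 2 + 0.5)/0.5 = 0
        g = make_genotypes(np.array([[1.0], [1.0]]))
        freqs = AlleleFrequencies(p=[0.5], n_obs=[2], snp_ids=["snp0"])
        grm = build_grm(g, freqs=freqs)
        assert grm.values[0, 0] == pytest.approx(0.0)

    def test_individual_at_mean_dosage_has_zero_off_diagonals(self, rng):
        d = rng.binomial(2, 0.5, size=(6, 30)).astype(float)
        d[0] = 1.0  # equals 2p when p is forced to 0.5 at every SNP
        freqs = AlleleFrequencies(p=np.full(30, 0.5), n_obs=np.full(30, 6),
                                  snp_ids=[f"snp{j}" for j in range(30)])
        grm = build_grm(make_genotypes(d), freqs=freqs)
        np.testing.assert_allclose(grm.values[0, 1:], 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p_true = rng.uniform(0.2, 0.8, size=50)
        d = rng.binomial(2, p_true, size=(20, 50)).astype(float)
        d[0] = 0.0
        d[1] = 2.0  # keep every column polymorphic
        g = make_genotypes(d)
        af = allele_frequencies(g)
        grm = build_grm(g)
        np.testing.assert_allclose(grm.values, naive_grm(d, af.p), atol=1e-10)

    def test_missing_dosage_contributes_zero_with_fixed_n(self):
        d = np.array([[2.0, 0.0], [0.0, 2.0], [1.0, np.nan]])
        g = make_genotypes(d)
        af = allele_frequencies(g)
        grm = build_grm(g)
        # pair (0,2): only SNP0 contributes for the missing SNP1, N stays 2
        het0 = 2 * af.p[0] * (1 - af.p[0])
        expect = ((2 - 2 * af.p[0]) * (1 - 2 * af.p[0]) / het0) / 2
        assert grm.values[0, 2] == pytest.approx(expect)

    def test_per_pair_n_divides_by_shared_count(self):
        d = np.array([[2.0, 0.0], [0.0, 2.0], [1.0, np.nan]])
        g = make_genotypes(d)
        af = allele_frequencies(g)
        grm = build_grm(g, per_pair_n=True)
        het0 = 2 * af.p[0] * (1 - af.p[0])
        expect = (2 - 2 * af.p[0]) * (1 - 2 * af.p[0]) / het0  # N_pair = 1
        assert grm.values[0, 2] == pytest.approx(expect)

    def test_monomorphic_snp_rejected(self):
        g = make_genotypes(np.array([[0.0, 2.0], [0.0, 0.0]]))
        with pytest.raises(MonomorphicSNPError, match="snp0"):
            build_grm(g)

    def test_empty_subset_rejected(self, random_panel):
        with pytest.raises(ValueError, match="empty"):
            build_grm(random_panel, snp_subset=[])


class TestThresholdGRM:
    def test_paper_boundary_cases(self):
        vals = np.array([[1.0, 0.04, 0.05], [0.04, 1.0, 0.06], [0.05, 0.06, 1.0]])
        grm = GRM(vals, ["a", "b", "c"], n_snps_used=100)
        out = threshold_grm(grm, 0.05)
        assert out.values[0, 1] == 0.0          # 0.04 <= t
        assert out.values[0, 2] == 0.0          # exactly t: "equal to or less than"
        assert out.values[1, 2] == 0.06         # above t: unchanged
        np.testing.assert_array_equal(np.diag(out.values), np.diag(vals))

    def test_negative_threshold_rejected(self):
        grm = GRM(np.eye(2), ["a", "b"], n_snps_used=1)
        with pytest.raises(ValueError, match=">= 0"):
            threshold_grm(grm, -0.1)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.5))
    def test_zeroes_exactly_the_off_diagonals_at_or_below_t(self, seed, t):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 8)
        half = rng.normal(scale=0.2, size=(n, n))
        vals = (half + half.T) / 2
        np.fill_diagonal(vals, 1.0)
        grm = GRM(vals, [f"i{k}" for k in range(n)], n_snps_used=10)
        out = threshold_grm(grm, t)
        off = ~np.eye(n, dtype=bool)
        assert np.all((out.values[off] == 0.0) == (vals[off] <= t))
        kept = off & (vals > t)
        np.testing.assert_array_equal(out.values[kept], vals[kept])
        # idempotent at fixed t
        out2 = threshold_grm(
            GRM(out.values, grm.ids, grm.n_snps_used), t
        )
        np.testing.assert_array_equal(out2.values, out.values)

    def test_threshold_zero_zeroes_only_non_positive(self):
        vals = np.array([[1.0, -0.1, 0.2], [-0.1, 1.0, 0.0], [0.2, 0.0, 1.0]])
        out = threshold_grm(GRM(vals, list("abc"), n_snps_used=5), 0.0)
        assert out.values[0, 1] == 0.0 and out.values[1, 2] == 0.0
        assert out.values[0, 2] == 0.2


class TestMafAndRegionSubsets:
    def make_freqs(self, ps):
        return AlleleFrequencies(p=np.array(ps), n_obs=np.full(len(ps), 10),
                                 snp_ids=[f"snp{j}" for j in range(len(ps))])

    def test_strict_boundary(self):
        freqs = self.make_freqs([0.951, 0.95, 0.3])
        snps = make_snp_table(3)
        ids = maf_subset(freqs, snps, 0.05)
        assert ids == ["snp0"]  # MAF 0.049 in, MAF 0.05 out (strict "under")

    def test_threshold_sets_are_nested(self, rng):
        freqs = self.make_freqs(rng.uniform(0.0001, 0.9999, size=200))
        snps = make_snp_table(200)
        sets = [set(maf_subset(freqs, snps, m))
                for m in (0.1, 0.05, 0.01, 0.005, 0.001)
                ]
        for smaller, larger in zip(sets[1:], sets):
            assert smaller <= larger

    def test_empty_result_is_error(self):
        freqs = self.make_freqs([0.5, 0.4])
        with pytest.raises(ValueError, match="no SNPs"):
            maf_subset(freqs, make_snp_table(2), 0.01)

    def test_region_interval_arithmetic_and_refusal(self):
        snps = make_snp_table(5, positions=[40, 60, 149, 251, 260])
        with pytest.raises(RegionTooSparseError, match="fewer than 10"):
            region_subset(snps, "1", 100, 200, flank_bp=50)
        ids = region_subset(snps, "1", 100, 200, flank_bp=50, min_snps=1)
        assert ids == ["snp1", "snp2"]

    def test_zero_flank_keeps_only_gene_span(self):
        snps = make_snp_table(5, positions=[40, 60, 149, 251, 260])
        ids = region_subset(snps, "1", 60, 150, flank_bp=0, min_snps=1)
        assert ids == ["snp1", "snp2"]

    def test_chromosome_only_mode(self):
        snps = pd.concat([make_snp_table(12, chromosome="1"),
                          make_snp_table(4, chromosome="2").assign(
                              snp_id=[f"c2_{j}" for j in range(4)])],
                         ignore_index=True)
        ids = region_subset(snps, "1")
        assert len(ids) == 12


class TestFhat3:
    def test_hand_values_at_half_frequency(self):
        freqs = AlleleFrequencies(p=[0.5], n_obs=[3], snp_ids=["snp0"])
        g = make_genotypes(np.array([[1.0], [0.0], [2.0]]))
        f = fhat3(g, freqs)
        assert f[0] == pytest.approx(-1.0)
        assert f[1] == pytest.approx(1.0)
        assert f[2] == pytest.approx(1.0)

    def test_equals_grm_diagonal_minus_one(self, random_panel):
        grm = build_grm(random_panel)
        np.testing.assert_allclose(
            fhat3(random_panel), np.diag(grm.values) - 1.0, atol=1e-12
        )

    def test_mean_near_zero_under_hardy_weinberg(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, size=3000)
        d = rng.binomial(2, p, size=(300, 3000)).astype(float)
        g = make_genotypes(d)
        f = fhat3(g)
        assert abs(f.mean()) < 0.01


class TestRelatednessSummary:
    def test_direct_count(self):
        vals = np.array([[1.0, 0.01, 0.2], [0.01, 1.0, 0.5], [0.2, 0.5, 1.0]])
        grm = GRM(vals, list("abc"), n_snps_used=10)
        s = relatedness_summary(grm, [0.05, 0.4])
        assert s.tolist() == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_all_zero_off_diagonals_in_lowest_bin(self):
        grm = GRM(np.eye(4), list("abcd"), n_snps_used=10)
        s = relatedness_summary(grm, [0.05, 0.4])
        assert s.iloc[0] == 1.0 and s.iloc[1:].sum() == 0.0

    def test_malformed_edges_rejected(self):
        grm = GRM(np.eye(3), list("abc"), n_snps_used=10)
        with pytest.raises(ValueError, match="increasing"):
            relatedness_summary(grm, [0.4, 0.05])
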