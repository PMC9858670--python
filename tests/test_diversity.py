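"""Diversity estimators against hand checks, published cells and oracles."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from mitodiv import (
    Alignment,
    coalescent_infinite_sites,
    esf_allele_count_pmf,
    ewens_expected_k,
    ewens_theta,
    ewens_theta_ci,
    haplotype_diversity,
    harmonic_numbers,
    mean_pairwise_differences,
    nucleotide_diversity,
    sample_esf_partition,
    segregating_sites,
    stirling1_unsigned,
    summarize,
    tajima_sd,
    watterson_theta,
)
from mitodiv.alignment import GroupAssignment

from conftest import random_alignment


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts, hd",
        [
            ((10, 2, 5), 0.588),                      # historical CR
            ((15, 6, 6), 0.615),                      # modern CR
            ((2, 2, 2, 4, 4, 1, 1, 1, 1, 1), 0.912),  # historical mitogenome
            ((6, 7, 3, 1, 4, 6, 1, 1), 0.852),        # modern mitogenome
        ],
    )
    def test_wolf_study_cells(self, counts, hd):
        assert round(haplotype_diversity(counts)[0], 3) == hd

    def test_monomorphic_is_zero(self):
        assert haplotype_diversity((7,)) == (0.0, 0.0)

    def test_modern_mitogenome_sd(self):
        assert round(haplotype_diversity((6, 7, 3, 1, 4, 6, 1, 1))[1], 3) == 0.030

    def test_rejects_singleton_sample(self):
        with pytest.raises(ValueError):
            haplotype_diversity((1,))


class TestPairwiseDifferences:
    def test_mean_of_three_pairs(self):
        # pairwise differences 1 (a,b), 2 (a,c), 3 (b,c) -> mean 2.0
        aln = Alignment.from_strings(
            ["a", "b", "c"], ["AAAAA", "AAAAT", "TTAAA"]
        )
        theta_pi, _ = mean_pairwise_differences(aln)
        assert theta_pi == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "theta, n, sd", [(2.43, 17, 1.55), (2.15, 27, 1.37), (12.83, 19, 6.76), (12.74, 29, 6.58)]
    )
    def test_tajima_sd_matches_table(self, theta, n, sd):
        assert round(tajima_sd(theta, n), 2) == sd

    def test_formula_matches_bruteforce_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            aln = random_alignment(rng, int(rng.integers(3, 12)), 30, n_missing=8)
            theta_pi, _ = mean_pairwise_differences(aln, "pairwise")
            seqs = list(aln.to_strings().values())
            miss = set("N-")
            dsum = 0
            for a, b in combinations(seqs, 2):
                dsum += sum(
                    1 for x, y in zip(a, b) if x != y and x not in miss and y not in miss
                )
            assert theta_pi == pytest.approx(dsum / (len(seqs) * (len(seqs) - 1) / 2))


class TestNucleotideDiversity:
    def test_modern_mitogenome_cell(self):
        pi, sd = nucleotide_diversity(12.74, 6.58, 15460)
        assert pi == pytest.approx(8.2e-4, abs=5e-6)
        assert sd == pytest.approx(4.3e-4, abs=5e-6)

    def test_zero_and_division(self):
        assert nucleotide_diversity(0.0, 0.0, 425) == (0.0, 0.0)
        assert nucleotide_diversity(2.15, 1.37, 425)[0] == pytest.approx(5.06e-3, abs=5e-6)


class TestSegregatingSites:
    def test_identical_and_simple(self):
        aln = Alignment.from_strings(["a", "b"], ["ACGT", "ACGT"])
        assert segregating_sites(aln) == 0
        aln = Alignment.from_strings(["a", "b"], ["ACGTAA", "TCGTCC"])
        assert segregating_sites(aln) == 3

    def test_missing_aware_policy(self):
        aln = Alignment.from_strings(["a", "b", "c"], ["ACGT", "ACGT", "NCGA"])
        assert segregating_sites(aln, "any_two_nonmissing") == 1
        assert segregating_sites(aln, "complete_only") == 1


class TestWatterson:
    @pytest.mark.parametrize("S, n, theta", [(41, 19, 11.73), (39, 29, 9.93), (6, 27, 1.56)])
    def test_table_cells(self, S, n, theta):
        assert round(watterson_theta(S, n)[0], 2) == theta

    def test_no_polymorphism(self):
        theta, sd = watterson_theta(0, 10)
        assert theta == 0.0 and sd == 0.0

    def test_unbiased_on_coalescent(self):
        # mean of S/a1 over many neutral genealogies approaches theta
        theta, n, reps = 3.0, 10, 2000
        rng_seeds = np.random.SeedSequence(42).spawn(reps)
        a1, a2 = harmonic_numbers(n)
        ests = np.empty(reps)
        for i, s in enumerate(rng_seeds):
            aln = coalescent_infinite_sites(n, theta, 200, s)
            ests[i] = segregating_sites(aln) / a1
        se = ests.std(ddof=1) / np.sqrt(reps)
        assert abs(ests.mean() - theta) < 3 * se


class TestEwensTheta:
    @pytest.mark.parametrize("n, K, theta", [(17, 3, 0.77), (27, 3, 0.64), (29, 8, 3.30)])
    def test_mle_cells(self, n, K, theta):
        assert round(ewens_theta(n, K), 2) == theta

    def test_degenerate_counts(self):
        assert ewens_theta(10, 1) == 0.0
        with pytest.raises(ValueError, match="unbounded"):
            ewens_theta(5, 5)
        assert ewens_theta(5, 5, on_saturated="inf") == np.inf
        with pytest.raises(ValueError):
            ewens_theta(5, 6)

    def test_monotone_in_k_and_self_consistent(self):
        n = 25
        thetas = [ewens_theta(n, k) for k in range(2, n)]
        assert all(a < b for a, b in zip(thetas, thetas[1:]))
        for k, t in zip(range(2, n), thetas):
            assert ewens_expected_k(t, n) == pytest.approx(k, abs=1e-7)


class TestEwensSamplingFormula:
    def test_stirling_row_n6(self):
        assert stirling1_unsigned(6) == (0, 120, 274, 225, 85, 15, 1)

    @pytest.mark.parametrize("n", [5, 12, 20])
    def test_stirling_generating_identity_exact(self, n):
        # sum_k |s(n,k)| t^k equals the rising factorial t(t+1)...(t+n-1)
        t = Fraction(7, 3)
        row = stirling1_unsigned(n)
        lhs = sum(Fraction(row[k]) * t**k for k in range(n + 1))
        rhs = Fraction(1)
        for i in range(n):
            rhs *= t + i
        assert lhs == rhs

    @pytest.mark.parametrize("n, theta", [(10, 0.5), (20, 3.0), (60, 11.7)])
    def test_pmf_normalizes(self, n, theta):
        assert esf_allele_count_pmf(theta, n).sum() == pytest.approx(1.0, abs=1e-12)


class TestEwensCI:
    def test_brackets_the_mle(self):
        for n, K in [(17, 3), (27, 3), (29, 8), (19, 10)]:
            lo, hi = ewens_theta_ci(n, K)
            assert lo <= ewens_theta(n, K) <= hi

    def test_single_haplotype_left_tail(self):
        lo, hi = ewens_theta_ci(12, 1)
        assert lo == 0.0 and hi > 0

    def test_saturated_right_tail_infinite(self):
        lo, hi = ewens_theta_ci(6, 6)
        assert np.isinf(hi) and lo > 0

    def test_n6_bounds_match_bruteforce_tail_inversion(self):
        # independent oracle: tails from the enumerated |s(6,k)| row
        from scipy.optimize import brentq

        s6 = (120, 274, 225, 85, 15, 1)  # k = 1..6

        def pmf(theta):
            rising = 1.0
            for i in range(6):
                rising *= theta + i
            return np.array([s6[k - 1] * theta**k / rising for k in range(1, 7)])

        lo_ref = brentq(lambda t: pmf(t)[2:].sum() - 0.025, 1e-9, 100)
        hi_ref = brentq(lambda t: pmf(t)[:3].sum() - 0.025, 1e-9, 1e5)
        lo, hi = ewens_theta_ci(6, 3)
        assert lo == pytest.approx(lo_ref, rel=1e-6)
        assert hi == pytest.approx(hi_ref, rel=1e-6)

    def test_coverage_of_true_theta(self):
        # ESF samples at theta=5: the 95% CI should cover >= 90% of 200 draws
        theta, n, reps = 5.0, 100, 200
        seeds = np.random.SeedSequence(11).spawn(reps)
        hits = 0
        for s in seeds:
            K = len(sample_esf_partition(theta, n, s))
            if K == n:
                continue
            lo, hi = ewens_theta_ci(n, K)
            hits += lo <= theta <= hi
        assert hits / reps >= 0.90


class TestSummarize:
    def test_two_group_summary(self, two_epoch_data):
        aln, groups = two_epoch_data
        rows = summarize(aln, groups)
        assert [r.group for r in rows] == ["historical", "modern"]
        for r in rows:
            assert r.theta_S == pytest.approx(r.S / r.a1)
            assert r.pi == pytest.approx(r.theta_pi / r.L_eff)
            assert 0 <= r.Hd <= 1
            assert r.theta_K_ci_low <= r.theta_K <= r.theta_K_ci_high

    def test_monomorphic_group(self):
        aln = Alignment.from_strings(["a", "b", "c", "d"], ["ACGT"] * 2 + ["ACGA"] * 2)
        groups = GroupAssignment({"a": "x", "b": "x", "c": "y", "d": "y"})
        rows = summarize(aln, groups)
        for r in rows:
            assert r.K == 1 and r.Hd == 0.0 and r.theta_K == 0.0 and r.S == 0


def test_hd_of_esf_sample_approaches_theta_over_one_plus_theta():
    # E[Hd] -> theta/(1+theta) for large n under the ESF
    theta, n, reps = 1.0, 500, 60
    seeds = np.random.SeedSequence(5).spawn(reps)
    hds = [haplotype_diversity(sample_esf_partition(theta, n, s))[0] for s in seeds]
    assert abs(np.mean(hds) - 0.5) < 0.05
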