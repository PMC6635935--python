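"""Nuclear-marker statistics: heterozygosities, HWE chain vs exact
enumeration, Fisher combination, Weir–Cockerham estimators vs an
independent component oracle, rarefied richness, and the LD test."""

import math

import numpy as np
import pytest

from armipop.data import GenotypeTable
from armipop.nuclear import (
    NotTestableError,
    allelic_richness,
    fisher_combine,
    fis_from_het,
    heterozygosities,
    hwe_exact_enumeration,
    hwe_mc_test,
    ld_test,
    locus_stats,
    wc_fstats,
)


def make_gt(rows, pops=None, locus="L"):
    rows = np.asarray(rows)
    n = len(rows)
    return GenotypeTable(
        [f"i{k}" for k in range(n)], [locus], rows.reshape(n, 1, 2),
        pops if pops is not None else ["p1"] * n,
    )


def levene_distribution(n11, n12, n22):
    """Oracle: exact conditional probabilities of all 2-allele tables
    with the observed allele counts, via integer combinatorics."""
    n = n11 + n12 + n22
    na = 2 * n11 + n12
    probs = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        i = (na - h) // 2
        j = n - i - h
        probs[h] = (
            2**h * math.factorial(n)
            // (math.factorial(i) * math.factorial(h) * math.factorial(j))
        )
    total = sum(probs.values())
    return {h: v / total for h, v in probs.items()}


class TestHeterozygosities:
    def test_unbiased_expected_het_from_counts(self):
        # gene counts (4,2,2) over n=4: He = (8/7)(1 - 0.375) = 0.714
        gt = make_gt([[1, 1], [1, 2], [2, 3], [1, 3]])
        he, ho = heterozygosities(gt, "L")
        assert he == pytest.approx(8 / 7 * 0.625)
        assert round(he, 3) == 0.714
        assert ho == 0.75

    def test_monomorphic(self):
        gt = make_gt([[5, 5], [5, 5]])
        he, ho = heterozygosities(gt, "L")
        assert he == 0.0 and ho == 0.0
        assert fis_from_het(he, ho) == 0.0

    def test_all_heterozygous_private_alleles(self):
        gt = make_gt([[1, 2], [3, 4], [5, 6]])
        _, ho = heterozygosities(gt, "L")
        assert ho == 1.0

    def test_allele_relabeling_invariance(self):
        a = make_gt([[1, 1], [1, 2], [2, 2]])
        b = make_gt([[9, 9], [7, 9], [7, 7]])
        assert heterozygosities(a, "L") == pytest.approx(
            heterozygosities(b, "L")
        )


class TestHweExact:
    def test_matches_levene_oracle(self):
        n11, n12, n22 = 10, 10, 30
        dist = levene_distribution(n11, n12, n22)
        p_obs = dist[n12]
        expected = sum(v for v in dist.values() if v <= p_obs * (1 + 1e-12))
        got = hwe_exact_enumeration({(1, 1): n11, (1, 2): n12, (2, 2): n22})
        assert got == pytest.approx(expected, rel=1e-9)

    def test_extreme_heterozygote_excess(self):
        p = hwe_exact_enumeration({(1, 2): 50})
        assert p < 0.001


class TestHweChain:
    def test_monomorphic_not_testable(self):
        gt = make_gt([[4, 4]] * 10)
        p, se = hwe_mc_test(gt, "L", seed=0)
        assert p == 1.0 and se == 0.0

    @pytest.mark.parametrize(
        "table", [(10, 10, 30), (25, 50, 25), (5, 25, 5)]
    )
    def test_chain_matches_exact_enumeration(self, table):
        n11, n12, n22 = table
        rows = [[1, 1]] * n11 + [[1, 2]] * n12 + [[2, 2]] * n22
        gt = make_gt(rows)
        exact = hwe_exact_enumeration({(1, 1): n11, (1, 2): n12, (2, 2): n22})
        p, se = hwe_mc_test(
            gt, "L", dememorization=2000, batches=50, iters_per_batch=2000,
            seed=7,
        )
        assert abs(p - exact) < 0.02

    def test_batch_se_reported(self):
        rows = [[1, 1]] * 10 + [[1, 2]] * 10 + [[2, 2]] * 10
        gt = make_gt(rows)
        p, se = hwe_mc_test(
            gt, "L", dememorization=500, batches=20, iters_per_batch=500, seed=1
        )
        assert 0 < p <= 1 and se >= 0


class TestFisher:
    def test_single_p_passes_through(self):
        chi2, df, p = fisher_combine([0.2])
        assert df == 2 and p == pytest.approx(0.2)

    def test_all_ones(self):
        chi2, df, p = fisher_combine([1.0, 1.0, 1.0])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_pair(self):
        chi2, df, p = fisher_combine([0.05, 0.05])
        assert chi2 == pytest.approx(-2 * (math.log(0.05) * 2))
        assert round(chi2, 2) == 11.98 and df == 4

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


def oracle_wc_components(genotypes, pops):
    """Independent Weir–Cockerham 1984 a/b/c sums (per allele, loops)."""
    labels = sorted(set(pops))
    r = len(labels)
    by_pop = {p: [g for g, q in zip(genotypes, pops) if q == p] for p in labels}
    n_i = {p: len(by_pop[p]) for p in labels}
    nbar = sum(n_i.values()) / r
    n_c = (r * nbar - sum(v * v for v in n_i.values()) / (r * nbar)) / (r - 1)
    alleles = sorted({a for g in genotypes for a in g})
    A = B = C = 0.0
    for al in alleles:
        p_i = {
            p: sum(int(g[0] == al) + int(g[1] == al) for g in by_pop[p])
            / (2 * n_i[p])
            for p in labels
        }
        h_i = {
            p: sum(int((g[0] == al) != (g[1] == al)) for g in by_pop[p]) / n_i[p]
            for p in labels
        }
        pbar = sum(n_i[p] * p_i[p] for p in labels) / (r * nbar)
        s2 = sum(n_i[p] * (p_i[p] - pbar) ** 2 for p in labels) / ((r - 1) * nbar)
        hbar = sum(n_i[p] * h_i[p] for p in labels) / (r * nbar)
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        A, B, C = A + a, B + b, C + hbar / 2
    return A, B, C


class TestWeirCockerham:
    def test_two_pops_fixed_for_different_alleles(self):
        rows = [[1, 1]] * 10 + [[2, 2]] * 10
        gt = make_gt(rows, pops=["A"] * 10 + ["B"] * 10)
        fs = wc_fstats(gt, n_perm=0)
        assert fs.Fst == pytest.approx(1.0)
        assert fs.Fit == pytest.approx(1.0)

    def test_all_homozygotes_one_population(self):
        gt = make_gt([[1, 1]] * 5 + [[2, 2]] * 5)
        fs = wc_fstats(gt, n_perm=0)
        assert fs.Fis == pytest.approx(1.0)
        assert math.isnan(fs.Fst)

    def test_matches_independent_component_oracle(self, rng):
        genotypes = [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(20)]
        pops = ["A"] * 10 + ["B"] * 10
        gt = make_gt([list(g) for g in genotypes], pops=pops)
        A, B, C = oracle_wc_components(genotypes, pops)
        fs = wc_fstats(gt, n_perm=0)
        assert fs.Fst == pytest.approx(A / (A + B + C), abs=1e-10)
        assert fs.Fis == pytest.approx(1 - C / (B + C), abs=1e-10)
        assert fs.Fit == pytest.approx(1 - C / (A + B + C), abs=1e-10)

    def test_consistency_identity(self, rng):
        genotypes = [list(sorted(rng.integers(1, 5, 2))) for _ in range(24)]
        pops = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
        gt = make_gt(genotypes, pops=pops)
        fs = wc_fstats(gt, n_perm=0)
        assert (1 - fs.Fit) == pytest.approx((1 - fs.Fis) * (1 - fs.Fst), abs=1e-12)

    def test_permutation_pvalues(self, rng):
        genotypes = [list(sorted(rng.integers(1, 3, 2))) for _ in range(16)]
        gt = make_gt(genotypes, pops=["A"] * 8 + ["B"] * 8)
        fs = wc_fstats(gt, n_perm=49, seed=5)
        assert 1 / 50 <= fs.p_values["Fst"] <= 1.0
        assert 1 / 50 <= fs.p_values["Fis"] <= 1.0


class TestAllelicRichness:
    def test_full_sample_returns_allele_count(self):
        gt = make_gt([[1, 1], [1, 2], [2, 3], [1, 3]])
        assert allelic_richness(gt, "L", g=8) == pytest.approx(3.0)

    def test_monomorphic_is_one(self):
        gt = make_gt([[2, 2]] * 6)
        assert allelic_richness(gt, "L", g=4) == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        gt = make_gt([[1, 1], [1, 2], [2, 3], [1, 3]])  # counts (4,2,2), N=8
        g = 6
        expected = sum(
            1 - math.comb(8 - c, g) / math.comb(8, g) for c in (4, 2, 2)
        )
        assert allelic_richness(gt, "L", g=g) == pytest.approx(expected)

    def test_monotone_in_g(self):
        gt = make_gt([[1, 1], [1, 2], [2, 3], [1, 3]])
        vals = [allelic_richness(gt, "L", g=g) for g in range(1, 9)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_g_out_of_range(self):
        gt = make_gt([[1, 2]])
        with pytest.raises(ValueError):
            allelic_richness(gt, "L", g=3)


class TestLdTest:
    def test_perfect_ld_floor_pvalue(self, rng):
        a = rng.integers(1, 4, 30)
        b = rng.integers(1, 4, 30)
        pair = np.sort(np.stack([a, b], axis=1), axis=1)
        geno = np.stack([pair, pair], axis=1)  # locus B duplicates locus A
        gt = GenotypeTable(
            [f"i{k}" for k in range(30)], ["A", "B"], geno, ["p"] * 30
        )
        lr, p = ld_test(gt, "A", "B", n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)
        assert lr > 0

    def test_em_on_double_homozygotes_reproduces_counting(self):
        # no phase ambiguity: haplotype frequencies are directly countable
        from armipop.nuclear import _em_haplotype_freqs

        ga = np.array([[1, 1], [1, 1], [2, 2], [2, 2]])
        gb = np.array([[5, 5], [6, 6], [5, 5], [6, 6]])
        h, _, (aa, bb) = _em_haplotype_freqs(ga, gb)
        counted = np.array([[0.25, 0.25], [0.25, 0.25]])
        assert np.allclose(h, counted)

    def test_independent_loci_give_large_pvalue(self, rng):
        n = 40
        ga = np.sort(rng.integers(1, 3, (n, 2)), axis=1)
        gb = np.sort(rng.integers(1, 3, (n, 2)), axis=1)
        geno = np.stack([ga, gb], axis=1)
        gt = GenotypeTable([f"i{k}" for k in range(n)], ["A", "B"], geno, ["p"] * n)
        _, p = ld_test(gt, "A", "B", n_perm=99, seed=3)
        assert p > 0.05

    def test_monomorphic_not_testable(self):
        geno = np.stack(
            [np.tile([1, 1], (6, 1)), np.sort(np.tile([1, 2], (6, 1)), axis=1)],
            axis=1,
        )
        gt = GenotypeTable([f"i{k}" for k in range(6)], ["A", "B"], geno, ["p"] * 6)
        with pytest.raises(NotTestableError):
            ld_test(gt, "A", "B", n_perm=9)


def test_locus_stats_assembles_consistent_row():
    rows = [[1, 1]] * 4 + [[1, 2]] * 8 + [[2, 2]] * 4
    gt = make_gt(rows)
    s = locus_stats(
        gt, "L",
        hwe_kwargs={"dememorization": 200, "batches": 10,
                    "iters_per_batch": 200, "seed": 0},
    )
    assert s.n == 16 and s.alleles == 2
    assert s.Fis == pytest.approx(1 - s.Ho / s.He)
    assert 0 < s.hwe_p <= 1 and s.hwe_testable
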