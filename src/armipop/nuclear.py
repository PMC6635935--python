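"""Codominant nuclear-marker statistics for the three EPIC loci
(DDC, RpS6, RpL11 scored as fragment lengths).

Covers observed/expected heterozygosity, the Markov-chain exact test of
Hardy–Weinberg proportions (Guo & Thompson style), Fisher's combined
probability across loci, Weir & Cockerham (1984) F-statistic estimators
with permutation tests, rarefied allelic richness, and a likelihood-ratio
test of gametic (linkage) disequilibrium with EM haplotype frequencies.

Missing genotypes are excluded locus-wise (pairwise deletion).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .data import GenotypeTable, InputError


class NotTestableError(ValueError):
    """A test cannot be run on this input (e.g. monomorphic locus)."""


@dataclass
class LocusStats:
    locus: str
    population: str | None
    n: int
    alleles: int
    richness: float
    He: float
    Ho: float
    Fis: float
    hwe_p: float
    hwe_se: float = float("nan")
    hwe_testable: bool = True


@dataclass
class GlobalFStats:
    """Weir & Cockerham multilocus estimators (θ = F_ST, f = F_IS, F = F_IT)."""

    Fst: float
    Fis: float
    Fit: float
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0


# ---------------------------------------------------------------------------
# Heterozygosities
# ---------------------------------------------------------------------------

def heterozygosities(
    gt: GenotypeTable, locus: str, population: str | None = None
) -> tuple[float, float]:
    """(He, Ho) at one locus.

    Ho is the fraction of heterozygous individuals; He is the unbiased
    expected heterozygosity over the 2n sampled genes,
    He = (2n/(2n−1)) (1 − Σ p_i²).
    """
    geno = gt.complete_genotypes(locus, population)
    if len(geno) == 0:
        raise NotTestableError(f"no complete genotypes at {locus}")
    ho = float(np.mean(geno[:, 0] != geno[:, 1]))
    genes = geno.ravel()
    ng = len(genes)
    _, counts = np.unique(genes, return_counts=True)
    p = counts / ng
    he = (ng / (ng - 1)) * (1.0 - float(np.sum(p**2))) if ng > 1 else 0.0
    return he, ho


def fis_from_het(He: float, Ho: float) -> float:
    """Locus-level inbreeding coefficient 1 − Ho/He (0 when He = 0)."""
    return 1.0 - Ho / He if He > 0 else 0.0


# ---------------------------------------------------------------------------
# Hardy–Weinberg Markov-chain exact test
# ---------------------------------------------------------------------------

def _table_logprob(counts: dict[tuple[int, int], int], het: int) -> float:
    """log conditional probability of a genotype table given allele counts,
    up to the constant n! Π n_i!/(2n)!:  H·ln2 − Σ ln a_ij!"""
    return het * math.log(2.0) - sum(
        float(gammaln(c + 1)) for c in counts.values()
    )


def hwe_exact_enumeration(genotype_counts: dict[tuple[int, int], int]) -> float:
    """Exact HWE p-value for a biallelic locus by full enumeration.

    Enumerates every genotype table compatible with the observed allele
    counts and sums the conditional probabilities of tables no more
    probable than the observed one.  Serves as the reference the Markov
    chain is checked against.
    """
    alleles = sorted({a for pair in genotype_counts for a in pair})
    if len(alleles) != 2:
        raise InputError("exact enumeration implemented for 2 alleles")
    a, b = alleles
    n11 = genotype_counts.get((a, a), 0)
    n12 = genotype_counts.get((a, b), 0) + genotype_counts.get((b, a), 0)
    n22 = genotype_counts.get((b, b), 0)
    n = n11 + n12 + n22
    na = 2 * n11 + n12

    def logp(h: int) -> float:
        i = (na - h) // 2
        j = n - i - h
        return h * math.log(2.0) - float(
            gammaln(i + 1) + gammaln(h + 1) + gammaln(j + 1)
        )

    hs = [h for h in range(na % 2, min(na, 2 * n - na) + 1, 2)]
    logps = np.array([logp(h) for h in hs])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(n12)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_mc_test(
    gt: GenotypeTable,
    locus: str,
    population: str | None = None,
    dememorization: int = 10000,
    batches: int = 1000,
    iters_per_batch: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Markov-chain estimate of the exact HWE p-value, with its s.e.

    The chain walks over genotype tables with the observed allele counts:
    each step swaps one allele between two random individuals, which keeps
    the conditional (Levene) distribution stationary.  The p-value is the
    long-run fraction of visited tables whose conditional probability is
    no greater than the observed table's; the standard error comes from
    batch means.  Monomorphic loci return p = 1 (not testable).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geno = gt.complete_genotypes(locus, population).copy()
    n = len(geno)
    if n < 2:
        raise NotTestableError(f"fewer than 2 complete genotypes at {locus}")
    if len(np.unique(geno)) < 2:
        return 1.0, 0.0

    counts: dict[tuple[int, int], int] = {}
    for a, b in geno:
        key = (int(a), int(b))
        counts[key] = counts.get(key, 0) + 1
    het = int(np.sum(geno[:, 0] != geno[:, 1]))
    logp = _table_logprob(counts, het)
    logp_obs = logp + 1e-9  # tolerate float noise on ties

    def step() -> None:
        nonlocal het, logp
        u, v = rng.integers(n), rng.integers(n)
        while v == u:
            v = rng.integers(n)
        pu, pv = int(rng.integers(2)), int(rng.integers(2))
        x, y = int(geno[u, pu]), int(geno[v, pv])
        if x == y:
            return
        old_u = (int(min(geno[u])), int(max(geno[u])))
        old_v = (int(min(geno[v])), int(max(geno[v])))
        geno[u, pu], geno[v, pv] = y, x
        new_u = (int(min(geno[u])), int(max(geno[u])))
        new_v = (int(min(geno[v])), int(max(geno[v])))
        for key, delta in ((old_u, -1), (old_v, -1), (new_u, 1), (new_v, 1)):
            c = counts.get(key, 0)
            logp += float(gammaln(c + 1))
            counts[key] = c + delta
            logp -= float(gammaln(c + delta + 1))
            if counts[key] == 0:
                del counts[key]
        d_het = (
            int(new_u[0] != new_u[1]) + int(new_v[0] != new_v[1])
            - int(old_u[0] != old_u[1]) - int(old_v[0] != old_v[1])
        )
        het += d_het
        logp += d_het * math.log(2.0)

    for _ in range(dememorization):
        step()
    batch_means = np.empty(batches)
    for b in range(batches):
        hits = 0
        for _ in range(iters_per_batch):
            step()
            if logp <= logp_obs:
                hits += 1
        batch_means[b] = hits / iters_per_batch
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(batches)) if batches > 1 else float("nan")
    if se >= 0.01:
        warnings.warn(
            f"HWE chain standard error {se:.3f} >= 0.01 at locus {locus}; "
            "increase batches or iterations",
            stacklevel=2,
        )
    return p, se


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's combined test: χ² = −2 Σ ln p on 2k df."""
    p_values = np.asarray(list(p_values), dtype=float)
    if len(p_values) == 0:
        raise InputError("no p-values to combine")
    if (p_values <= 0).any() or (p_values > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.sum(np.log(p_values)))
    df = 2 * len(p_values)
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Weir & Cockerham F-statistics
# ---------------------------------------------------------------------------

def _wc_components(gt: GenotypeTable, pop_labels: np.ndarray):
    """Per-locus, per-allele variance components (a, b, c) summed.

    Returns (sum_a, sum_b, sum_c) over all loci and alleles, using the
    1984 method-of-moments formulas with unequal sample sizes.
    """
    sum_a = sum_b = sum_c = 0.0
    pops = np.unique(pop_labels)
    for l, locus in enumerate(gt.loci):
        geno = gt.genotypes[:, l]
        complete = (geno != -1).all(axis=1)
        if not complete.any():
            continue
        g = geno[complete]
        labels = pop_labels[complete]
        keep_pops = [p for p in pops if np.sum(labels == p) >= 1]
        r = len(keep_pops)
        if r < 1:
            continue
        n_i = np.array([np.sum(labels == p) for p in keep_pops], dtype=float)
        nbar = n_i.mean()
        # with one population the among-populations component is undefined
        n_c = (
            (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1) if r > 1 else 1.0
        )
        alleles = np.unique(g)
        for allele in alleles:
            # frequency and heterozygote frequency per population
            p_i = np.empty(r)
            h_i = np.empty(r)
            for k, p in enumerate(keep_pops):
                sub = g[labels == p]
                p_i[k] = np.mean(sub == allele)
                h_i[k] = np.mean((sub[:, 0] == allele) ^ (sub[:, 1] == allele))
            pbar = float(np.sum(n_i * p_i) / (r * nbar))
            s2 = (
                float(np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar))
                if r > 1 else 0.0
            )
            hbar = float(np.sum(n_i * h_i) / (r * nbar))
            if nbar <= 1:
                continue
            if r > 1:
                a = (nbar / n_c) * (
                    s2
                    - (1.0 / (nbar - 1))
                    * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
                )
            else:
                a = 0.0
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2.0
            sum_a += a
            sum_b += b
            sum_c += c
    return sum_a, sum_b, sum_c


def _wc_theta(sum_a, sum_b, sum_c) -> float:
    tot = sum_a + sum_b + sum_c
    return sum_a / tot if tot != 0 else 0.0


def _wc_f(sum_b, sum_c) -> float:
    bc = sum_b + sum_c
    return 1.0 - sum_c / bc if bc != 0 else 0.0


def wc_fstats(
    gt: GenotypeTable,
    pop_labels=None,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> GlobalFStats:
    """Multilocus Weir & Cockerham F-statistics with permutation tests.

    θ (F_ST) is tested by permuting whole individuals among populations;
    f (F_IS) by permuting alleles among individuals within populations.
    Both use upper-tailed p = (b+1)/(B+1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.array(pop_labels if pop_labels is not None else gt.pop_labels)
    multi_pop = len(np.unique(labels)) >= 2
    sum_a, sum_b, sum_c = _wc_components(gt, labels)
    theta = _wc_theta(sum_a, sum_b, sum_c) if multi_pop else float("nan")
    f = _wc_f(sum_b, sum_c)
    tot = sum_a + sum_b + sum_c
    F = 1.0 - sum_c / tot if tot != 0 else 0.0
    p_values: dict[str, float] = {}
    if n_perm:
        ge_theta = ge_f = 0
        for _ in range(n_perm):
            if multi_pop:
                perm = labels[rng.permutation(len(labels))]
                pa, pb, pc = _wc_components(gt, perm)
                if _wc_theta(pa, pb, pc) >= theta:
                    ge_theta += 1
            shuffled = _shuffle_alleles_within_pops(gt, labels, rng)
            qa, qb, qc = _wc_components(shuffled, labels)
            if _wc_f(qb, qc) >= f:
                ge_f += 1
        p_values = {"Fis": (ge_f + 1) / (n_perm + 1)}
        if multi_pop:
            p_values["Fst"] = (ge_theta + 1) / (n_perm + 1)
    return GlobalFStats(Fst=theta, Fis=f, Fit=F, p_values=p_values,
                        n_permutations=n_perm)


def _shuffle_alleles_within_pops(
    gt: GenotypeTable, labels: np.ndarray, rng: np.random.Generator
) -> GenotypeTable:
    """Re-pair gene copies at random within each population, per locus."""
    geno = gt.genotypes.copy()
    for l in range(len(gt.loci)):
        for p in np.unique(labels):
            idx = np.flatnonzero(labels == p)
            complete = idx[(geno[idx, l] != -1).all(axis=1)]
            if len(complete) < 2:
                continue
            genes = geno[complete, l].ravel()
            genes = genes[rng.permutation(len(genes))]
            geno[complete, l] = genes.reshape(-1, 2)
    return GenotypeTable(list(gt.ids), list(gt.loci), geno, list(gt.pop_labels))


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

def allelic_richness(
    gt: GenotypeTable, locus: str, population: str | None = None,
    g: int | None = None,
) -> float:
    """Rarefied allelic richness at gene-sample size ``g``.

    Rs = Σ_alleles [1 − C(N−N_i, g) / C(N, g)] — the expected number of
    distinct alleles in a random draw of ``g`` gene copies from the ``N``
    sampled ones.  By default ``g`` is twice the smallest per-population
    count of typed individuals, the usual rarefaction base.
    """
    genes = gt.alleles_at(locus, population)
    N = len(genes)
    if N == 0:
        raise NotTestableError(f"no complete genotypes at {locus}")
    if g is None:
        sizes = []
        for p in set(gt.pop_labels):
            k = len(gt.alleles_at(locus, p))
            if k:
                sizes.append(k)
        g = min(sizes)
    if g < 1 or g > N:
        raise ValueError(f"rarefaction size g={g} outside [1, N={N}]")
    _, counts = np.unique(genes, return_counts=True)
    denom = math.comb(N, g)
    return float(sum(1.0 - math.comb(N - int(c), g) / denom if N - c >= g else 1.0
                     for c in counts))


# ---------------------------------------------------------------------------
# Linkage disequilibrium (EM likelihood-ratio test)
# ---------------------------------------------------------------------------

def _em_haplotype_freqs(ga: np.ndarray, gb: np.ndarray,
                        max_iter: int = 200, tol: float = 1e-10):
    """EM estimate of two-locus haplotype frequencies from unphased
    diploid genotypes.  Returns (freqs dict, lnL at the MLE)."""
    alleles_a = sorted(set(ga.ravel().tolist()))
    alleles_b = sorted(set(gb.ravel().tolist()))
    ia = {a: i for i, a in enumerate(alleles_a)}
    ib = {b: i for i, b in enumerate(alleles_b)}
    ra, rb = len(alleles_a), len(alleles_b)
    h = np.full((ra, rb), 1.0 / (ra * rb))
    m = len(ga)

    # per-individual phase configurations: ((a1,b1),(a2,b2)) pairs
    configs = []
    for (a1, a2), (b1, b2) in zip(ga, gb):
        c1 = ((ia[a1], ib[b1]), (ia[a2], ib[b2]))
        c2 = ((ia[a1], ib[b2]), (ia[a2], ib[b1]))
        configs.append((c1,) if c1 == c2 or frozenset(c1) == frozenset(c2) else (c1, c2))

    def pair_prob(cfg, hf):
        (x1, y1), (x2, y2) = cfg
        p = hf[x1, y1] * hf[x2, y2]
        return 2.0 * p if (x1, y1) != (x2, y2) else p

    lnl = -np.inf
    for _ in range(max_iter):
        counts = np.zeros_like(h)
        new_lnl = 0.0
        for cfgs in configs:
            probs = np.array([pair_prob(c, h) for c in cfgs])
            tot = probs.sum()
            if tot <= 0:
                tot = 1e-300
            new_lnl += math.log(tot)
            w = probs / tot
            for weight, ((x1, y1), (x2, y2)) in zip(w, cfgs):
                counts[x1, y1] += weight
                counts[x2, y2] += weight
        h = counts / (2.0 * m)
        if abs(new_lnl - lnl) < tol:
            lnl = new_lnl
            break
        lnl = new_lnl
    return h, lnl, (alleles_a, alleles_b)


def _lnl_independent(ga: np.ndarray, gb: np.ndarray) -> float:
    """Log-likelihood with haplotype freqs = products of allele freqs."""
    alleles_a, ca = np.unique(ga.ravel(), return_counts=True)
    alleles_b, cb = np.unique(gb.ravel(), return_counts=True)
    pa = dict(zip(alleles_a.tolist(), ca / ca.sum()))
    pb = dict(zip(alleles_b.tolist(), cb / cb.sum()))
    lnl = 0.0
    for (a1, a2), (b1, b2) in zip(ga, gb):
        c1 = ((a1, b1), (a2, b2))
        c2 = ((a1, b2), (a2, b1))
        cfgs = (c1,) if frozenset(c1) == frozenset(c2) else (c1, c2)
        tot = 0.0
        for (x1, y1), (x2, y2) in cfgs:
            p = pa[x1] * pb[y1] * pa[x2] * pb[y2]
            tot += 2.0 * p if (x1, y1) != (x2, y2) else p
        lnl += math.log(max(tot, 1e-300))
    return lnl


def ld_test(
    gt: GenotypeTable,
    locus_a: str,
    locus_b: str,
    population: str | None = None,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Likelihood-ratio test of gametic disequilibrium between two loci.

    Haplotype frequencies are estimated by EM (phase unknown);
    LR = 2 (lnL_assoc − lnL_indep).  The null distribution comes from
    permuting one locus' genotypes across individuals, breaking the
    between-locus association while preserving both single-locus tables.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = gt.population_mask(population)
    la, lb = gt.locus_index(locus_a), gt.locus_index(locus_b)
    ga_all = gt.genotypes[mask, la]
    gb_all = gt.genotypes[mask, lb]
    complete = (ga_all != -1).all(axis=1) & (gb_all != -1).all(axis=1)
    ga, gb = ga_all[complete], gb_all[complete]
    if len(ga) < 2:
        raise NotTestableError("fewer than two doubly typed individuals")
    if len(np.unique(ga)) < 2 or len(np.unique(gb)) < 2:
        raise NotTestableError("monomorphic locus")
    _, lnl1, _ = _em_haplotype_freqs(ga, gb)
    lr_obs = 2.0 * (lnl1 - _lnl_independent(ga, gb))
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(gb))
        gbp = gb[perm]
        _, lnl1p, _ = _em_haplotype_freqs(ga, gbp)
        lr = 2.0 * (lnl1p - _lnl_independent(ga, gbp))
        if lr >= lr_obs:
            ge += 1
    return lr_obs, (ge + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def locus_stats(
    gt: GenotypeTable,
    locus: str,
    population: str | None = None,
    g: int | None = None,
    hwe_kwargs: dict | None = None,
) -> LocusStats:
    """Full per-locus, per-population summary (one report cell)."""
    he, ho = heterozygosities(gt, locus, population)
    geno = gt.complete_genotypes(locus, population)
    alleles = len(np.unique(geno))
    testable = alleles >= 2
    if testable:
        p, se = hwe_mc_test(gt, locus, population, **(hwe_kwargs or {}))
    else:
        p, se = 1.0, 0.0
    return LocusStats(
        locus=locus,
        population=population,
        n=len(geno),
        alleles=alleles,
        richness=allelic_richness(gt, locus, population, g=g),
        He=he,
        Ho=ho,
        Fis=fis_from_het(he, ho),
        hwe_p=p,
        hwe_se=se,
        hwe_testable=testable,
    )
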