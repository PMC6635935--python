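"""Haplotype and nucleotide diversity, segregating sites, Watterson's theta,
transition/transversion counts, and the mutation-rate calibration arithmetic
used to bound coalescent priors.

All sequence statistics use complete deletion: columns containing a gap or
an IUPAC ambiguity in any sequence are removed alignment-wide before
counting, so the effective length ``L`` is the number of clean columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Alignment, HaplotypeSpectrum, collapse_haplotypes

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this input (e.g. n < 2, S = 0)."""


@dataclass
class DiversityResult:
    """Per-population diversity summary (one row of the standard report)."""

    n: int
    k: int
    Hd: float
    Hd_sd: float
    pi: float
    pi_sd: float
    S: int
    thetaW_locus: float
    ts: int
    tv: int


# ---------------------------------------------------------------------------
# Haplotype diversity (Nei's unbiased estimator)
# ---------------------------------------------------------------------------

def haplotype_diversity(
    spectrum: HaplotypeSpectrum, population: str | None = None
) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its standard deviation.

    Hd = n (1 − Σ p_i²) / (n − 1), with sampling variance

    V(Hd) = [2 / (n(n−1))] { 2(n−2)[Σ p_i³ − (Σ p_i²)²] + Σ p_i² − (Σ p_i²)² }

    computed from the haplotype relative frequencies ``p_i`` of the chosen
    population (pooled over all populations when ``population is None``).
    """
    counts = spectrum.column(population)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if n < 2:
        raise UndefinedStatisticError(f"haplotype diversity needs n >= 2 (n={n})")
    p = counts / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    hd = n * (1.0 - sum2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    return hd, float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def _pairwise_diff_counts(seqs: np.ndarray) -> np.ndarray:
    """Condensed vector of pairwise difference counts between rows."""
    n = seqs.shape[0]
    out = np.empty(n * (n - 1) // 2, dtype=int)
    k = 0
    for i in range(n - 1):
        d = (seqs[i + 1:] != seqs[i]).sum(axis=1)
        out[k: k + len(d)] = d
        k += len(d)
    return out


def mean_pairwise_differences(aln: Alignment) -> float:
    """Mean number of pairwise differences (per locus) after complete deletion."""
    if aln.n < 2:
        raise UndefinedStatisticError("needs n >= 2 sequences")
    clean = aln.complete_deletion()
    return float(_pairwise_diff_counts(clean.seqs).mean())


def nucleotide_diversity(
    aln: Alignment, population: str | None = None, by: str = "region"
) -> tuple[float, float]:
    """Per-site nucleotide diversity π and its standard deviation.

    π is the mean proportion of differing sites over all sequence pairs,
    using the complete-deletion effective length.  The standard deviation
    combines the sampling and stochastic variance of π (Tajima's formula,
    the one reported by the standard sequence-analysis programs):

    V(π) = (n+1) π / (3(n−1) L) + 2 (n² + n + 3) π² / (9 n (n−1)).
    """
    if population is not None:
        aln = aln.population(population, by="pop" if by == "pop" else "region")
    if aln.n < 2:
        raise UndefinedStatisticError("nucleotide diversity needs n >= 2")
    clean = aln.complete_deletion()
    L = clean.length
    if L == 0:
        return 0.0, 0.0
    pi = float(_pairwise_diff_counts(clean.seqs).mean()) / L
    n = aln.n
    var = (n + 1) * pi / (3.0 * (n - 1) * L) + (
        2.0 * (n * n + n + 3) * pi * pi / (9.0 * n * (n - 1))
    )
    return pi, float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# Segregating sites and Watterson's theta
# ---------------------------------------------------------------------------

def segregating_sites(aln: Alignment) -> int:
    """Number of polymorphic columns after complete deletion."""
    if aln.n < 2:
        raise UndefinedStatisticError("segregating sites needs n >= 2")
    clean = aln.complete_deletion()
    if clean.length == 0:
        return 0
    return int((clean.seqs != clean.seqs[0]).any(axis=0).sum())


def harmonic_number(m: int) -> float:
    """a1 = Σ_{i=1}^{m} 1/i."""
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def watterson_theta(aln: Alignment, per_site: bool = False) -> float:
    """Watterson's θ = S / a1, per locus by default.

    The per-locus value is what feeds the coalescent-prior calibration;
    pass ``per_site=True`` to divide by the effective length.
    """
    S = segregating_sites(aln)
    theta = S / harmonic_number(aln.n - 1)
    if per_site:
        L = aln.complete_deletion().length
        theta = theta / L if L else 0.0
    return theta


def ts_tv_counts(aln: Alignment) -> tuple[int, int]:
    """Transition and transversion counts over variable sites.

    Each variable site contributes one count per unordered pair of distinct
    bases observed there: a biallelic site adds to exactly one class; a
    triallelic site contributes per base pair present.
    """
    clean = aln.complete_deletion()
    ts = tv = 0
    for j in range(clean.length):
        bases = sorted(set(clean.seqs[:, j]))
        for a in range(len(bases)):
            for b in range(a + 1, len(bases)):
                if frozenset((bases[a], bases[b])) in TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    return ts, tv


# ---------------------------------------------------------------------------
# Calibration arithmetic (theta -> Ne -> tau)
# ---------------------------------------------------------------------------

def ne_from_theta(theta: float, rate: float, L: int) -> float:
    """Effective population size from per-locus theta: Ne = θ / (rate × L).

    ``rate`` is in substitutions/site/year and ``L`` in bp, so ``rate × L``
    is the per-locus yearly rate.  This is the plain θ = Ne µ arithmetic
    used to calibrate the coalescent priors; note it carries no ploidy
    factor (mtDNA convention would be θ = 2 Ne µ) — the calibration is
    reproduced as defined, not "corrected".
    """
    if theta <= 0 or rate <= 0 or L <= 0:
        raise ValueError("theta, rate and L must all be positive")
    return theta / (rate * L)


def tau_from_generations(n_generations: float, Ne: float) -> float:
    """Coalescent-scaled age: tau = generations / (2 Ne)."""
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    if n_generations < 0:
        raise ValueError("generation count must be non-negative")
    return n_generations / (2.0 * Ne)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def diversity_summary(aln: Alignment, population: str | None = None,
                      by: str = "region") -> DiversityResult:
    """All diversity statistics for one population (or pooled)."""
    sub = aln if population is None else aln.population(
        population, by="pop" if by == "pop" else "region"
    )
    spec = collapse_haplotypes(sub, by="all")
    hd, hd_sd = haplotype_diversity(spec)
    pi, pi_sd = nucleotide_diversity(sub)
    S = segregating_sites(sub)
    ts, tv = ts_tv_counts(sub)
    return DiversityResult(
        n=sub.n,
        k=spec.n_haplotypes,
        Hd=hd,
        Hd_sd=hd_sd,
        pi=pi,
        pi_sd=pi_sd,
        S=S,
        thetaW_locus=watterson_theta(sub),
        ts=ts,
        tv=tv,
    )
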