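"""Synthetic datasets with the statistical structure of the real study.

Everything downstream is testable without any download:

* :func:`table1_fixture` — the published haplotype × region count table
  (303 concatenated-mtDNA individuals, 54 haplotypes, 7 regions) embedded
  as code constants;
* :func:`table1_alignment` — an alignment engineered to collapse exactly
  to that spectrum (haplotype *identities* are synthetic: each haplotype
  is tagged by a private site, so only the frequency structure is real);
* :func:`gen_mtdna_dataset` — coalescent mtDNA with a recent rapid
  expansion, the demographic signature the real data show (negative
  Tajima's D, unimodal mismatch);
* :func:`gen_genotype_table` — three-locus diploid tables with one
  low-diversity locus and two many-allele loci, drawn at a chosen
  inbreeding coefficient F_IS;
* :func:`gen_pods` — pseudo-observed SuSt vectors with recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import coalescent
from .data import Alignment, GenotypeTable, HaplotypeSpectrum
from .inference import ModelSpec, SuStVector, compute_sust

REGIONS = ["AM", "AM/CE", "CE/CA", "CE", "AT", "PA", "Puerto Rico"]

#: Printed per-region haplotype counts (row = haplotype, column = region).
_TABLE1: dict[str, dict[str, int]] = {
    "AM": {"H1": 3, "H2": 2, "H3": 1, "H4": 1, "H5": 2, "H7": 1, "H9": 1,
           "H10": 1, "H14": 1, "H17": 1, "H46": 1, "H47": 1},
    "AM/CE": {"H1": 1, "H3": 3, "H4": 1, "H5": 3, "H7": 3, "H9": 2,
              "H10": 1, "H11": 1, "H13": 1, "H16": 1, "H17": 1,
              "H42": 1, "H43": 1, "H44": 1, "H45": 1},
    "CE/CA": {"H1": 24, "H2": 17, "H3": 10, "H4": 12, "H5": 9, "H6": 12,
              "H7": 3, "H8": 5, "H9": 4, "H10": 2, "H11": 1, "H12": 2,
              "H14": 2, "H16": 1, "H19": 1, "H20": 1, "H21": 2, "H22": 1,
              **{f"H{i}": 1 for i in range(24, 29)},
              **{f"H{i}": 1 for i in range(32, 42)}},
    "CE": {"H1": 7, "H2": 11, "H3": 4, "H4": 2, "H5": 4, "H6": 5, "H7": 1,
           "H8": 3, "H9": 1, "H10": 3, "H11": 1, "H12": 1, "H13": 1,
           "H14": 1, "H17": 1, "H18": 2, "H19": 1, "H22": 1, "H29": 1,
           "H30": 1},
    "AT": {"H1": 8, "H2": 8, "H3": 8, "H4": 6, "H5": 3, "H6": 3, "H7": 2,
           "H8": 1, "H9": 1, "H11": 1, "H12": 1, "H13": 3, "H15": 3,
           "H20": 1, "H23": 2, "H31": 1, "H51": 1, "H52": 1, "H53": 1,
           "H54": 1},
    "PA": {"H1": 3, "H2": 4, "H3": 4, "H4": 1, "H5": 1, "H6": 2, "H7": 2,
           "H8": 2, "H9": 1, "H10": 1, "H11": 1, "H12": 1, "H14": 1,
           "H15": 1, "H17": 1, "H48": 1, "H49": 1, "H50": 1},
    "Puerto Rico": {"H1": 2, "H16": 2},
}


def table1_fixture() -> HaplotypeSpectrum:
    """The published 54-haplotype × 7-region count table (n = 303)."""
    hap_ids = [f"H{i}" for i in range(1, 55)]
    counts = np.array(
        [[_TABLE1[r].get(h, 0) for r in REGIONS] for h in hap_ids], dtype=int
    )
    return HaplotypeSpectrum(hap_ids, counts, list(REGIONS))


def table1_alignment(L: int = 1646) -> Alignment:
    """An alignment that collapses exactly to the published spectrum.

    Synthetic sequences: every haplotype Hk (k > 1) carries a private
    derived base at column k−1 of an otherwise constant background, so
    identical frequency structure is guaranteed while the actual
    haplotype genealogy is not emulated.
    """
    spec = table1_fixture()
    if L <= spec.n_haplotypes:
        raise ValueError("L must exceed the number of haplotypes")
    base = ["A"] * L
    hap_seqs: dict[str, str] = {}
    for k, hap in enumerate(spec.haplotype_ids):
        row = list(base)
        if k > 0:
            row[k] = "T"
        hap_seqs[hap] = "".join(row)
    ids, seqs, pops, regions = [], [], [], []
    counter = 0
    for j, region in enumerate(spec.population_ids):
        for hap, c in zip(spec.haplotype_ids, spec.counts[:, j]):
            for _ in range(int(c)):
                counter += 1
                ids.append(f"ind{counter:03d}")
                seqs.append(hap_seqs[hap])
                pops.append(region)
                regions.append(region)
    return Alignment.from_strings(ids, seqs, pops, regions)


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

#: AT-rich composition typical of insect mitochondrial genes.
MTDNA_COMPOSITION = {"A": 0.31, "C": 0.15, "G": 0.15, "T": 0.39}


def _default_spectra() -> dict[str, np.ndarray]:
    """Per-locus allele-frequency spectra: two many-allele loci (DDC- and
    RpS6-like) and one nearly monomorphic locus (RpL11-like)."""
    geom18 = 0.75 ** np.arange(18)
    geom14 = 0.72 ** np.arange(14)
    return {
        "DDC": geom18 / geom18.sum(),
        "RpL11": np.array([0.95, 0.05]),
        "RpS6": geom14 / geom14.sum(),
    }


def _default_allele_sizes() -> dict[str, np.ndarray]:
    return {
        "DDC": np.arange(170, 170 + 18 * 8, 8),
        "RpL11": np.array([120, 124]),
        "RpS6": np.arange(215, 215 + 14 * 5, 5),
    }


@dataclass
class GeneratorConfig:
    """Study-shaped defaults for the synthetic generators.

    Region sizes copy the published sampling (16/22/124/52/56/29/4 over
    seven morphoclimatic regions, total 303); the mtDNA demography is a
    recent rapid expansion (mutational age ``tau``, pre-/post-expansion
    mutation-scaled sizes ``theta0``/``theta1``) — the regime the real
    data's neutrality tests and unimodal mismatch indicate.
    """

    n_per_region: dict[str, int] = field(
        default_factory=lambda: dict(zip(REGIONS, [16, 22, 124, 52, 56, 29, 4]))
    )
    sites_per_region: int = 2
    L: int = 1646
    tau: float = 3.5
    theta0: float = 1.0
    theta1: float = 100.0
    base_composition: dict[str, float] = field(
        default_factory=lambda: dict(MTDNA_COMPOSITION)
    )
    ts_bias: float = 0.9
    nuclear_spectra: dict[str, np.ndarray] = field(default_factory=_default_spectra)
    nuclear_allele_sizes: dict[str, np.ndarray] = field(
        default_factory=_default_allele_sizes
    )
    fis: float = 0.13

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.n_per_region.values()):
            raise ValueError("region sizes must be positive")
        if self.theta0 <= 0 or self.theta1 <= 0 or self.tau < 0:
            raise ValueError("invalid expansion parameters")
        for locus, p in self.nuclear_spectra.items():
            p = np.asarray(p, dtype=float)
            if abs(p.sum() - 1) > 1e-8 or (p <= 0).any():
                raise ValueError(f"invalid spectrum for {locus}")
            pmin = p.min()
            if not (-pmin / (1 - pmin) - 1e-12 <= self.fis <= 1):
                raise ValueError(
                    f"fis={self.fis} outside admissible range for locus {locus}"
                )

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_region.values()))

    def demographic_model(self, theta: float | None = None) -> coalescent.DemographicModel:
        th1 = self.theta1 if theta is None else theta
        t_event = self.tau / th1  # mutational age on the 2N-generation scale
        return coalescent.DemographicModel(
            family="expansion",
            n_samples=(self.n_total,),
            theta=th1,
            expansion_events=[(t_event, self.theta0 / th1)],
            L=self.L,
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_mtdna_dataset(cfg: GeneratorConfig, seed: int | np.random.Generator = 0) -> Alignment:
    """Labelled mtDNA alignment under the expansion demography.

    Individuals are assigned region (and within-region site) labels in
    the configured proportions; the genealogy itself is panmictic, which
    matches the study system's lack of spatial structure.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sim = coalescent.simulate(cfg.demographic_model(), rng)
    aln = coalescent.realize_sequences(
        sim, L=cfg.L, base_composition=cfg.base_composition,
        ts_bias=cfg.ts_bias, seed=rng,
    )
    pops, regions = [], []
    for region, n_r in cfg.n_per_region.items():
        for i in range(n_r):
            site_no = (i * cfg.sites_per_region) // n_r + 1 if n_r >= cfg.sites_per_region else 1
            pops.append(f"{region}-s{site_no}")
            regions.append(region)
    aln.pop_labels = pops
    aln.region_labels = regions
    return aln


def gen_genotype_table(cfg: GeneratorConfig, seed: int | np.random.Generator = 0) -> GenotypeTable:
    """Three-locus diploid genotypes at inbreeding coefficient ``cfg.fis``.

    Genotype probabilities are P(hom i) = p_i² + F p_i(1−p_i) and
    P(het ij) = 2 p_i p_j (1−F), drawn per individual per locus.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = list(cfg.nuclear_spectra)
    n = cfg.n_total
    geno = np.zeros((n, len(loci), 2), dtype=int)
    for l, locus in enumerate(loci):
        p = np.asarray(cfg.nuclear_spectra[locus], dtype=float)
        sizes = np.asarray(cfg.nuclear_allele_sizes[locus], dtype=int)
        k = len(p)
        pairs = [(i, j) for i in range(k) for j in range(i, k)]
        probs = np.array([
            p[i] ** 2 + cfg.fis * p[i] * (1 - p[i]) if i == j
            else 2.0 * p[i] * p[j] * (1 - cfg.fis)
            for i, j in pairs
        ])
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        draws = rng.choice(len(pairs), size=n, p=probs)
        for row, d in enumerate(draws):
            i, j = pairs[d]
            geno[row, l] = sorted((sizes[i], sizes[j]))
    ids = [f"ind{i + 1:03d}" for i in range(n)]
    pops = []
    for region, n_r in cfg.n_per_region.items():
        pops.extend([region] * n_r)
    return GenotypeTable(ids, loci, geno, pops)


def gen_pods(
    model: ModelSpec, n_pods: int, seed: int | np.random.Generator = 0
) -> list[tuple[SuStVector, dict[str, float]]]:
    """Pseudo-observed datasets from a model's prior, with recorded truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pods = []
    for _ in range(n_pods):
        params = model.draw_params(rng)
        sim = coalescent.simulate(model.build(params), rng)
        pods.append((compute_sust(sim), params))
    return pods
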