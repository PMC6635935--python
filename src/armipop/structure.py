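"""Hierarchical analysis of molecular variance (AMOVA) and pairwise Φ_ST.

Variance in pairwise sequence differences is partitioned among sites
(2-level) or among regions / among sites within regions / within sites
(3-level), following the sums-of-squared-differences decomposition with
the standard unequal-sample-size coefficients.  The molecular distance is
the plain count of differing sites (no rate-heterogeneity correction,
i.e. a gamma-a parameter of zero) squared into the SS terms — for 0/1 or
nucleotide data the squared Euclidean distance *is* the difference count.

Significance comes from label permutations with the (b+1)/(B+1)
correction; each Φ statistic uses its own permutation scheme:

* Φ_ST — individuals permuted among sites;
* Φ_CT — whole sites permuted among regions;
* Φ_SC — individuals permuted among sites within their region.

Negative variance components are reported as estimated and enter the
percentage normalization (sample noise around a true value near zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Alignment, InputError, Partition


@dataclass
class AmovaResult:
    levels: dict[str, float]  # named variance components
    percent: dict[str, float]
    phi: dict[str, float]
    df: dict[str, int]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0


@dataclass
class PairwiseFstMatrix:
    labels: list[str]
    values: np.ndarray
    p_values: np.ndarray
    excluded: list[str] = field(default_factory=list)


def squared_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise difference counts after complete deletion (δ²)."""
    clean = aln.complete_deletion()
    seqs = clean.seqs
    n = seqs.shape[0]
    d = np.zeros((n, n))
    for i in range(n - 1):
        diffs = (seqs[i + 1:] != seqs[i]).sum(axis=1)
        d[i, i + 1:] = diffs
        d[i + 1:, i] = diffs
    return d


def _ss_within(d2: np.ndarray, groups: np.ndarray) -> float:
    """Σ over groups of (1/n_g) Σ_{i<j in g} δ²_ij."""
    total = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
    return total


def _two_level_components(d2: np.ndarray, pops: np.ndarray):
    """(sigma_a, sigma_w, df) for the among/within-sites decomposition."""
    n_tot = len(pops)
    labels, counts = np.unique(pops, return_counts=True)
    P = len(labels)
    ss_total = d2.sum() / (2.0 * n_tot)
    ss_wp = _ss_within(d2, pops)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, n_tot - P
    ms_ap = ss_ap / df_ap if df_ap else 0.0
    ms_wp = ss_wp / df_wp if df_wp else 0.0
    n_c = (n_tot - np.sum(counts**2) / n_tot) / df_ap if df_ap else 1.0
    sigma_w = ms_wp
    sigma_a = (ms_ap - ms_wp) / n_c if n_c else 0.0
    return sigma_a, sigma_w, {"among_sites": df_ap, "within_sites": df_wp}


def _phi_from(sigma_a: float, sigma_w: float) -> float:
    tot = sigma_a + sigma_w
    return sigma_a / tot if tot > 0 else 0.0


def _three_level_components(d2: np.ndarray, pops: np.ndarray, groups: np.ndarray):
    """(sigma_a, sigma_b, sigma_c, df) for regions/sites/individuals."""
    n_tot = len(pops)
    pop_labels = np.unique(pops)
    grp_labels = np.unique(groups)
    P, G = len(pop_labels), len(grp_labels)
    grp_of_pop = {}
    for p, g in zip(pops, groups):
        grp_of_pop[p] = g
    ss_total = d2.sum() / (2.0 * n_tot)
    ss_wp = _ss_within(d2, pops)
    ss_wg = _ss_within(d2, groups)
    ssd_ag = ss_total - ss_wg
    ssd_ap = ss_wg - ss_wp
    df = {"among_regions": G - 1, "among_sites_within_regions": P - G,
          "within_sites": n_tot - P}
    ms_ag = ssd_ag / df["among_regions"] if df["among_regions"] else 0.0
    ms_ap = ssd_ap / df["among_sites_within_regions"] if df["among_sites_within_regions"] else 0.0
    ms_wp = ss_wp / df["within_sites"] if df["within_sites"] else 0.0

    # unequal-sample-size coefficients
    n_pg = {}
    N_g = {}
    for p in pop_labels:
        n_p = int(np.sum(pops == p))
        g = grp_of_pop[p]
        n_pg[p] = n_p
        N_g[g] = N_g.get(g, 0) + n_p
    sum_npg2_over_Ng = sum(
        sum(n_pg[p] ** 2 for p in pop_labels if grp_of_pop[p] == g) / N_g[g]
        for g in grp_labels
    )
    sum_npg2_over_N = sum(n_pg[p] ** 2 for p in pop_labels) / n_tot
    sum_Ng2_over_N = sum(v**2 for v in N_g.values()) / n_tot
    n1 = (n_tot - sum_npg2_over_Ng) / (P - G) if P > G else 1.0
    n2 = (sum_npg2_over_Ng - sum_npg2_over_N) / (G - 1) if G > 1 else 1.0
    n3 = (n_tot - sum_Ng2_over_N) / (G - 1) if G > 1 else 1.0

    sigma_c = ms_wp
    # with one site per region the among-sites-within level is empty
    sigma_b = (ms_ap - sigma_c) / n1 if (n1 and P > G) else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if n3 else 0.0
    return sigma_a, sigma_b, sigma_c, df


def amova(
    aln: Alignment,
    partition: Partition | None = None,
    levels: int = 2,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> AmovaResult:
    """AMOVA over the sampling hierarchy of ``partition``.

    ``levels=2`` partitions variance among/within sites; ``levels=3`` adds
    the region level above sites.  Sites with a single individual are kept
    (they contribute df to the among level); an analysis needs at least
    two sites, and 3 levels need at least two regions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if partition is None:
        partition = Partition.from_alignment(aln)
    pops = np.array(partition.site_labels(aln.ids))
    if len(np.unique(pops)) < 2:
        raise InputError("AMOVA needs at least two sites")
    d2 = squared_distance_matrix(aln)

    if levels == 2:
        sigma_a, sigma_w, df = _two_level_components(d2, pops)
        phi_st = _phi_from(sigma_a, sigma_w)
        ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(pops)
            pa, pw, _ = _two_level_components(d2, perm)
            if _phi_from(pa, pw) >= phi_st:
                ge += 1
        tot = sigma_a + sigma_w
        pct = {
            "among_sites": 100.0 * sigma_a / tot if tot else 0.0,
            "within_sites": 100.0 * sigma_w / tot if tot else 0.0,
        }
        return AmovaResult(
            levels={"among_sites": sigma_a, "within_sites": sigma_w},
            percent=pct,
            phi={"phi_st": phi_st},
            df=df,
            p_values={"phi_st": (ge + 1) / (n_perm + 1)} if n_perm else {},
            n_permutations=n_perm,
        )

    if levels != 3:
        raise InputError("levels must be 2 or 3")
    groups = np.array(partition.region_labels(aln.ids))
    if len(np.unique(groups)) < 2:
        raise InputError("3-level AMOVA needs at least two regions")
    sigma_a, sigma_b, sigma_c, df = _three_level_components(d2, pops, groups)
    tot = sigma_a + sigma_b + sigma_c
    phi = {
        "phi_ct": sigma_a / tot if tot > 0 else 0.0,
        "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0,
        "phi_st": (sigma_a + sigma_b) / tot if tot > 0 else 0.0,
    }
    p_values: dict[str, float] = {}
    if n_perm:
        ge = {"phi_ct": 0, "phi_sc": 0, "phi_st": 0}
        site_list = list(dict.fromkeys(pops))
        region_of = {s: partition.region_of_site[s] for s in site_list}
        region_values = [region_of[s] for s in site_list]
        site_index = {s: i for i, s in enumerate(site_list)}
        region_labels_all = np.array(list(region_of.values()))
        for _ in range(n_perm):
            # phi_st: individuals among sites (regions follow sites)
            perm_idx = rng.permutation(len(pops))
            p_pops = pops[perm_idx]
            p_groups = np.array([region_of[s] for s in p_pops])
            a1, b1, c1, _ = _three_level_components(d2, p_pops, p_groups)
            t1 = a1 + b1 + c1
            if ((a1 + b1) / t1 if t1 > 0 else 0.0) >= phi["phi_st"]:
                ge["phi_st"] += 1
            # phi_ct: whole sites among regions
            perm_regions = rng.permutation(region_values)
            reg_of_site = dict(zip(site_list, perm_regions))
            p_groups2 = np.array([reg_of_site[s] for s in pops])
            a2, b2, c2, _ = _three_level_components(d2, pops, p_groups2)
            t2 = a2 + b2 + c2
            if (a2 / t2 if t2 > 0 else 0.0) >= phi["phi_ct"]:
                ge["phi_ct"] += 1
            # phi_sc: individuals among sites within regions
            p_pops3 = pops.copy()
            for g in np.unique(region_labels_all):
                idx = np.flatnonzero(groups == g)
                p_pops3[idx] = pops[idx][rng.permutation(len(idx))]
            a3, b3, c3, _ = _three_level_components(d2, p_pops3, groups)
            if (b3 / (b3 + c3) if (b3 + c3) > 0 else 0.0) >= phi["phi_sc"]:
                ge["phi_sc"] += 1
        p_values = {k: (v + 1) / (n_perm + 1) for k, v in ge.items()}
    pct = {
        "among_regions": 100.0 * sigma_a / tot if tot else 0.0,
        "among_sites_within_regions": 100.0 * sigma_b / tot if tot else 0.0,
        "within_sites": 100.0 * sigma_c / tot if tot else 0.0,
    }
    return AmovaResult(
        levels={
            "among_regions": sigma_a,
            "among_sites_within_regions": sigma_b,
            "within_sites": sigma_c,
        },
        percent=pct,
        phi=phi,
        df=df,
        p_values=p_values,
        n_permutations=n_perm,
    )


def pairwise_phist(
    aln: Alignment,
    partition: Partition | None = None,
    level: str = "region",
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> PairwiseFstMatrix:
    """Pairwise Φ_ST between populations (sites or regions).

    Each cell is a two-population AMOVA Φ_ST on the pair's individuals;
    negative estimates are retained.  Populations with fewer than two
    individuals are excluded and reported in ``excluded``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if partition is None:
        partition = Partition.from_alignment(aln)
    if level == "region":
        labels = np.array(partition.region_labels(aln.ids))
    else:
        labels = np.array(partition.site_labels(aln.ids))
    uniq = list(dict.fromkeys(labels))
    sizes = {u: int(np.sum(labels == u)) for u in uniq}
    excluded = [u for u in uniq if sizes[u] < 2]
    keep = [u for u in uniq if sizes[u] >= 2]
    d2_full = squared_distance_matrix(aln)
    k = len(keep)
    values = np.zeros((k, k))
    p_values = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            idx = np.flatnonzero(np.isin(labels, [keep[i], keep[j]]))
            sub = d2_full[np.ix_(idx, idx)]
            sub_labels = labels[idx]
            sa, sw, _ = _two_level_components(sub, sub_labels)
            # retain the raw (possibly negative) estimate
            tot = sa + sw
            phi = sa / tot if tot != 0 else 0.0
            ge = 0
            for _ in range(n_perm):
                perm = rng.permutation(sub_labels)
                pa, pw, _ = _two_level_components(sub, perm)
                ptot = pa + pw
                if (pa / ptot if ptot != 0 else 0.0) >= phi:
                    ge += 1
            values[i, j] = values[j, i] = phi
            if n_perm:
                p_values[i, j] = p_values[j, i] = (ge + 1) / (n_perm + 1)
    return PairwiseFstMatrix(
        labels=keep, values=values, p_values=p_values, excluded=excluded
    )
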