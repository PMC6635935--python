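"""Two-deme coalescent simulator with infinite-sites mutation.

Implements the three demographic families used by the invasion-origin
model choice:

* ``constant`` — constant population size;
* ``growth`` — exponential population growth in the sampled demes
  (backward in time the demes shrink at rate ``alpha``);
* ``expansion`` — very rapid (instantaneous) population expansion, encoded
  as step size changes placed before and after the divergence time.

Scaling: θ = 4N₀µ per locus, deme sizes relative to N₀, and time in
units of 2N₀ generations — a deme of relative size ``x`` coalesces each
lineage pair at rate ``1/x`` (so ``k`` lineages at ``k(k−1)/(2x)``) and
mutations are Poisson with mean θ·T_total/2 over the realized total
branch length, falling uniformly on branches (infinite sites: every
mutation is a new column).  These two rules jointly give the standard
expectations E[pairwise differences] = θ and E[S] = θ·Σ 1/i; note the
time unit they imply is 2N₀ generations, so a printed age computed as
generations/(2Ne) is already on this scale.

Migration is deliberately absent from all families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import Alignment


class ModelError(ValueError):
    """Invalid demographic model specification."""


@dataclass
class DemographicModel:
    """Demography of one simulated scenario.

    Parameters
    ----------
    family
        ``"constant"``, ``"growth"`` or ``"expansion"``.
    n_samples
        Per-deme sample sizes; one entry = single-deme model, two entries =
        two-deme model with a divergence event.
    theta
        θ = 4N₀µ per locus.
    t_div
        Divergence time in units of 2N₀ generations (two-deme models only).
        Looking backward, at ``t_div`` the second deme merges into the first.
    growth_rate
        Exponential growth rate α (``growth`` family); sampled demes have
        relative size exp(−α·t) backward in time until ``t_div``, after
        which the ancestral deme is constant at size 1.
    expansion_events
        ``(time, size_ratio)`` pairs (``expansion`` family): at each time,
        looking backward, every active deme's relative size is set to
        ``size_ratio``.  A ratio ≪ 1 encodes a very rapid forward-time
        expansion at that epoch.
    L
        Locus length in bp (used when realizing sequences).
    """

    family: str = "constant"
    n_samples: tuple[int, ...] = (10,)
    theta: float = 1.0
    t_div: float | None = None
    growth_rate: float = 0.0
    expansion_events: list[tuple[float, float]] = field(default_factory=list)
    L: int = 626

    def __post_init__(self) -> None:
        if self.family not in {"constant", "growth", "expansion"}:
            raise ModelError(f"unknown family {self.family!r}")
        if not self.n_samples or any(n < 1 for n in self.n_samples):
            raise ModelError("each deme needs at least one sample")
        if len(self.n_samples) > 2:
            raise ModelError("at most two demes are supported")
        if self.theta < 0:
            raise ModelError("theta must be non-negative")
        if len(self.n_samples) == 2:
            if self.t_div is None or self.t_div <= 0:
                raise ModelError("two-deme models need t_div > 0")
        if self.family == "growth" and self.growth_rate < 0:
            raise ModelError("growth rate must be non-negative")
        if self.family == "expansion":
            times = [t for t, _ in self.expansion_events]
            if any(t < 0 for t in times):
                raise ModelError("event times must be non-negative")
            if sorted(times) != times:
                raise ModelError("expansion events must be time-ordered")
            if any(r <= 0 for _, r in self.expansion_events):
                raise ModelError("size ratios must be positive")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_samples))


@dataclass
class SimulatedSample:
    """One realized sample: 0/1 haplotypes at segregating sites."""

    genotypes: np.ndarray  # (n, S) 0/1
    positions: np.ndarray  # (S,) in (0, 1)
    demes: np.ndarray  # (n,) deme index per row
    tree_height: float
    total_branch_length: float
    L: int = 626

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def S(self) -> int:
        return self.genotypes.shape[1]


# ---------------------------------------------------------------------------
# Genealogy sampling
# ---------------------------------------------------------------------------

def _waiting_time(k: int, x: float, alpha: float, t: float, t_ref: float,
                  rng: np.random.Generator) -> float:
    """Time to next coalescence among k lineages in a deme of size
    x·exp(−alpha·(t−t_ref)); infinite when k < 2."""
    if k < 2:
        return math.inf
    pairs = k * (k - 1) / 2.0
    rate0 = pairs / x
    e = rng.exponential()
    if alpha == 0.0:
        return e / rate0
    # backward size shrinks, hazard grows: invert the cumulative hazard
    z = math.exp(alpha * (t - t_ref))
    return (1.0 / alpha) * math.log(z + e * alpha * x / pairs) - (t - t_ref)


def _sample_genealogy(model: DemographicModel, rng: np.random.Generator):
    """Run the structured coalescent; return (branches, height).

    ``branches`` is a list of ``(length, leaf_indices)``; a mutation on a
    branch is carried by exactly its subtended leaves.
    """
    two_demes = len(model.n_samples) == 2
    lineages: list[list[list[int]]] = []  # per deme: list of leaf-index lists
    offset = 0
    for nd in model.n_samples:
        lineages.append([[offset + i] for i in range(nd)])
        offset += nd
    birth: list[dict[int, float]] = [
        {id(l): 0.0 for l in deme} for deme in lineages
    ]
    # per-deme size state: (size, alpha, t_ref)
    if model.family == "growth":
        sizes = [[1.0, model.growth_rate, 0.0] for _ in lineages]
    else:
        sizes = [[1.0, 0.0, 0.0] for _ in lineages]

    # schedule of demographic events, time-ordered
    schedule: list[tuple[float, str, float]] = []
    if model.family == "expansion":
        for t_ev, ratio in model.expansion_events:
            schedule.append((t_ev, "resize", ratio))
    if two_demes:
        schedule.append((model.t_div, "merge", 0.0))
    schedule.sort(key=lambda ev: ev[0])

    branches: list[tuple[float, list[int]]] = []
    t = 0.0
    birth_times: dict[int, float] = {}
    for deme in lineages:
        for l in deme:
            birth_times[id(l)] = 0.0

    def total_lineages() -> int:
        return sum(len(d) for d in lineages)

    while total_lineages() > 1:
        waits = [
            _waiting_time(len(deme), s[0], s[1], t, s[2], rng)
            for deme, s in zip(lineages, sizes)
        ]
        d_min = int(np.argmin(waits))
        t_next = t + waits[d_min]
        if schedule and schedule[0][0] < t_next:
            t_ev, kind, payload = schedule.pop(0)
            t = t_ev
            if kind == "resize":
                for s in sizes:
                    s[0], s[1], s[2] = payload, 0.0, t_ev
            else:  # merge demes
                lineages[0].extend(lineages[1])
                lineages[1] = []
                if model.family == "growth":
                    # the exponential regime spans the divergence: the
                    # ancestral population keeps size exp(-alpha t)
                    sizes[0] = [1.0, model.growth_rate, 0.0]
                else:
                    sizes[0] = [1.0, 0.0, t_ev]
                sizes = sizes[:1]
                lineages = lineages[:1]
            continue
        # coalescence in deme d_min
        t = t_next
        deme = lineages[d_min]
        i, j = rng.choice(len(deme), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        a, b = deme[i], deme[j]
        branches.append((t - birth_times[id(a)], a))
        branches.append((t - birth_times[id(b)], b))
        merged = a + b
        deme[i] = merged
        del deme[j]
        birth_times[id(merged)] = t

    return branches, t


def simulate(model: DemographicModel, seed: int | np.random.Generator) -> SimulatedSample:
    """Simulate one sample under ``model``.

    Mutation count is Poisson(θ·T_total/2); each mutation picks a branch
    with probability proportional to its length and becomes one segregating
    column, at a fresh uniform position in (0, 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    branches, height = _sample_genealogy(model, rng)
    lengths = np.array([b[0] for b in branches])
    total = float(lengths.sum())
    n = model.n_total
    n_mut = rng.poisson(model.theta * total / 2.0) if total > 0 else 0
    return _place_mutations(model, branches, lengths, total, height, n_mut, rng)


def simulate_fixed_s(
    n: int,
    S: int,
    seed: int | np.random.Generator,
    model: DemographicModel | None = None,
) -> SimulatedSample:
    """Simulate with exactly ``S`` mutations on the realized genealogy.

    This is the fixed-S null used to assign p-values to Tajima's D and
    Fu's Fs: the genealogy comes from the (by default constant-size,
    single-deme) coalescent and ``S`` mutations fall uniformly on the
    total branch length.
    """
    if S < 0:
        raise ModelError("S must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model is None:
        model = DemographicModel(family="constant", n_samples=(n,), theta=0.0)
    elif model.n_total != n:
        raise ModelError("model sample size disagrees with n")
    branches, height = _sample_genealogy(model, rng)
    lengths = np.array([b[0] for b in branches])
    total = float(lengths.sum())
    return _place_mutations(model, branches, lengths, total, height, S, rng)


def _place_mutations(model, branches, lengths, total, height, n_mut, rng):
    n = model.n_total
    demes = np.repeat(np.arange(len(model.n_samples)), model.n_samples)
    if n_mut == 0 or total == 0:
        return SimulatedSample(
            genotypes=np.zeros((n, 0), dtype=np.int8),
            positions=np.zeros(0),
            demes=demes,
            tree_height=height,
            total_branch_length=total,
            L=model.L,
        )
    probs = lengths / total
    hit = rng.choice(len(branches), size=n_mut, p=probs)
    positions = np.sort(rng.random(n_mut))
    geno = np.zeros((n, n_mut), dtype=np.int8)
    for col, b in enumerate(hit):
        geno[branches[b][1], col] = 1
    return SimulatedSample(
        genotypes=geno,
        positions=positions,
        demes=demes,
        tree_height=height,
        total_branch_length=total,
        L=model.L,
    )


# ---------------------------------------------------------------------------
# Sequence realization and ms-style serialization
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def realize_sequences(
    sim: SimulatedSample,
    L: int | None = None,
    base_composition: dict[str, float] | None = None,
    ts_bias: float = 0.9,
    seed: int | np.random.Generator = 0,
    ids: list[str] | None = None,
) -> Alignment:
    """Turn 0/1 segregating sites into a nucleotide alignment.

    Each mutation is assigned a distinct integer site in ``[0, L)``; the
    ancestral base is drawn from ``base_composition`` and the derived base
    is a transition with probability ``ts_bias``, otherwise one of the two
    transversions, equiprobably.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if L is None:
        L = sim.L
    if sim.S > L:
        raise ModelError(f"more segregating sites ({sim.S}) than bp ({L})")
    comp = base_composition or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    bases = list(comp)
    probs = np.array([comp[b] for b in bases], dtype=float)
    probs = probs / probs.sum()
    ancestral = rng.choice(bases, size=L, p=probs)
    seqs = np.tile(ancestral, (sim.n, 1)).astype("U1")
    site_idx = rng.choice(L, size=sim.S, replace=False)
    site_idx.sort()
    for col, j in enumerate(site_idx):
        anc = str(ancestral[j])
        if rng.random() < ts_bias:
            derived = _TRANSITION[anc]
        else:
            derived = _TRANSVERSIONS[anc][int(rng.integers(2))]
        carriers = sim.genotypes[:, col] == 1
        seqs[carriers, j] = derived
    if ids is None:
        ids = [f"ind{i + 1}" for i in range(sim.n)]
    pop = [f"deme{d + 1}" for d in sim.demes]
    return Alignment(ids=ids, seqs=seqs, pop_labels=pop, region_labels=list(pop))


def to_ms_block(sim: SimulatedSample) -> str:
    """Serialize one sample as an ms-style text block."""
    lines = ["//", f"segsites: {sim.S}"]
    if sim.S:
        lines.append("positions: " + " ".join(f"{p:.5f}" for p in sim.positions))
        lines.extend("".join(str(int(v)) for v in row) for row in sim.genotypes)
    return "\n".join(lines) + "\n"


def from_ms_block(text: str, demes: tuple[int, ...] | None = None, L: int = 626) -> SimulatedSample:
    """Parse one ms-style block back into a :class:`SimulatedSample`."""
    lines = [l for l in text.strip().splitlines() if l and l != "//"]
    S = int(lines[0].split(":")[1])
    if S == 0:
        raise ModelError("cannot infer sample size from an S=0 ms block")
    positions = np.array([float(x) for x in lines[1].split(":")[1].split()])
    rows = [list(map(int, l.strip())) for l in lines[2:]]
    geno = np.array(rows, dtype=np.int8)
    n = geno.shape[0]
    deme_arr = (
        np.repeat(np.arange(len(demes)), demes) if demes else np.zeros(n, dtype=int)
    )
    return SimulatedSample(
        genotypes=geno,
        positions=positions,
        demes=deme_arr,
        tree_height=float("nan"),
        total_branch_length=float("nan"),
        L=L,
    )
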