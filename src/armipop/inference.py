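"""Rejection-ABC model choice over two-deme coalescent scenarios.

The pipeline mirrors the invasion-origin design: three demographic model
families (constant size / exponential growth / rapid expansion) are
simulated per scenario under uniform priors, summary statistics (SuSt)
are collected into a reference table, and a rejection step retains the
simulations closest (Euclidean distance on SD-standardized statistics)
to the observed SuSt; posterior model probabilities are the retained
models' shares, reported on the 0–100 scale.  Around this sit: a
cross-validated choice of which SuSt subset best discriminates the
models (scored on pseudo-observed datasets), a PCA goodness-of-fit
check, prior restriction to the weighted 2.5–97.5% posterior interval,
and a final hierarchical run comparing each scenario's best model.

Summary statistics are: pooled per-site nucleotide diversity (pi),
pooled segregating sites (SS), pooled Tajima's D (D), per-deme
nucleotide diversity (pi_w_*), and between-deme diversity (pi_b_*).
A simulated sample with S = 0 has no defined D; it is encoded as 0 with
a companion validity flag kept outside the candidate-statistic set, so
vectors remain fixed-length.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coalescent
from .data import Alignment
from .diversity import UndefinedStatisticError
from .neutrality import tajimas_d_parts


class AbcError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SuStVector:
    """Named summary-statistic vector for one (observed or simulated) sample."""

    names: list[str]
    values: np.ndarray
    d_defined: bool = True

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def subset(self, names) -> np.ndarray:
        idx = [self.names.index(n) for n in names]
        return self.values[idx]


def _pairwise_mean_within(geno: np.ndarray) -> float:
    n = geno.shape[0]
    if n < 2:
        return float("nan")
    c = geno.sum(axis=0).astype(float)
    return float(np.sum(c * (n - c)) / (n * (n - 1) / 2.0))


def _pairwise_mean_between(ga: np.ndarray, gb: np.ndarray) -> float:
    na, nb = ga.shape[0], gb.shape[0]
    ca = ga.sum(axis=0).astype(float)
    cb = gb.sum(axis=0).astype(float)
    diff = ca * (nb - cb) + cb * (na - ca)
    return float(diff.sum() / (na * nb))


def compute_sust(sample, partition=None) -> SuStVector:
    """SuSt for a :class:`~armipop.coalescent.SimulatedSample` or an
    :class:`~armipop.data.Alignment` (deme = population label).

    All diversities are per site (divided by L).  A deme with fewer than
    two samples has no within diversity and is flagged by NaN there.
    """
    if isinstance(sample, Alignment):
        return _sust_from_alignment(sample)
    sim = sample
    L = float(sim.L)
    n = sim.n
    geno = sim.genotypes
    S = sim.S
    pi_locus = _pairwise_mean_within(geno) if n >= 2 else float("nan")
    names = ["pi", "SS"]
    values = [pi_locus / L, float(S)]
    d_defined = True
    try:
        d = tajimas_d_parts(n, S, pi_locus)
    except UndefinedStatisticError:
        d, d_defined = 0.0, False
    names.append("D")
    values.append(d)
    deme_ids = np.unique(sim.demes)
    for d_id in deme_ids:
        sub = geno[sim.demes == d_id]
        names.append(f"pi_w_{d_id + 1}")
        values.append(_pairwise_mean_within(sub) / L)
    for a, b in itertools.combinations(deme_ids, 2):
        names.append(f"pi_b_{a + 1}_{b + 1}")
        values.append(
            _pairwise_mean_between(geno[sim.demes == a], geno[sim.demes == b]) / L
        )
    return SuStVector(names, np.array(values, dtype=float), d_defined)


def _sust_from_alignment(aln: Alignment) -> SuStVector:
    from .diversity import _pairwise_diff_counts, segregating_sites

    clean = aln.complete_deletion()
    L = float(clean.length)
    n = aln.n
    diffs_all = _pairwise_diff_counts(clean.seqs)
    pi_locus = float(diffs_all.mean()) if n >= 2 else float("nan")
    S = segregating_sites(aln)
    names = ["pi", "SS"]
    values = [pi_locus / L, float(S)]
    d_defined = True
    try:
        d = tajimas_d_parts(n, S, pi_locus)
    except UndefinedStatisticError:
        d, d_defined = 0.0, False
    names.append("D")
    values.append(d)
    demes = list(dict.fromkeys(aln.pop_labels))
    masks = {p: np.array([l == p for l in aln.pop_labels]) for p in demes}
    for k, p in enumerate(demes):
        sub = clean.seqs[masks[p]]
        if sub.shape[0] >= 2:
            piw = float(_pairwise_diff_counts(sub).mean()) / L
        else:
            piw = float("nan")
        names.append(f"pi_w_{k + 1}")
        values.append(piw)
    for (ka, pa), (kb, pb) in itertools.combinations(enumerate(demes), 2):
        sa, sb = clean.seqs[masks[pa]], clean.seqs[masks[pb]]
        tot = 0
        for row in sa:
            tot += int((sb != row).sum())
        names.append(f"pi_b_{ka + 1}_{kb + 1}")
        values.append(tot / (sa.shape[0] * sb.shape[0]) / L)
    return SuStVector(names, np.array(values, dtype=float), d_defined)


# ---------------------------------------------------------------------------
# Model specifications and priors
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """One demographic model family plus its (uniform) parameter priors.

    ``theta_bounds`` defaults to (0, 4.123] — the Watterson estimate from
    the observed locus is the prior maximum — and ``t_div_bounds`` to
    (0, 3.274]: the calibrated maximum coalescence age in units of 2Ne
    generations, which is exactly the simulator's time scale, so the
    printed value is used unconverted.

    The rapid-expansion family places one instantaneous size change on
    each side of the divergence: at ``f1·min(t_div, w)`` (the invading
    deme's founder-to-outbreak expansion, after the split in forward
    time) and at ``t_div + f2·w`` (the source population's expansion
    shortly before the split), where ``w = event_window``.  Tying event
    ages to the recent epoch (within ~Ne generations, w = 0.5) rather
    than to the full tree depth is what makes the family mean what it
    says: every draw is a *recent, very rapid* expansion, the hypothesis
    the scenario encodes, instead of an arbitrarily deep size change no
    sample statistic could see.  The (0.001, 0.1] ratio prior spans ten-
    to thousand-fold forward-time expansions.  The growth prior is
    bounded so that total exponential growth over the maximum coalescence
    depth stays in that same magnitude range (e^{2.5·3.274} ≈ 3600×);
    steeper rates degenerate into an instantaneous collapse that no
    summary statistic can tell apart from an arbitrarily extreme step
    expansion.
    """

    name: str
    family: str = "constant"
    n_samples: tuple[int, ...] = (36, 40)
    L: int = 626
    theta_bounds: tuple[float, float] = (1e-3, 4.123)
    t_div_bounds: tuple[float, float] = (1e-3, 3.274)
    event_window: float = 0.5
    alpha_bounds: tuple[float, float] = (0.05, 2.5)
    ratio_bounds: tuple[float, float] = (1e-3, 0.1)
    frac_bounds: tuple[float, float] = (0.05, 0.95)

    def param_names(self) -> list[str]:
        names = ["theta"]
        if len(self.n_samples) == 2:
            names.append("t_div")
        if self.family == "growth":
            names.append("alpha")
        if self.family == "expansion":
            names += ["f1", "r1", "f2", "r2"]
        return names

    def draw_params(self, rng: np.random.Generator) -> dict[str, float]:
        draw = lambda lo, hi: float(rng.uniform(lo, hi))
        params = {"theta": draw(*self.theta_bounds)}
        if len(self.n_samples) == 2:
            params["t_div"] = draw(*self.t_div_bounds)
        if self.family == "growth":
            params["alpha"] = draw(*self.alpha_bounds)
        if self.family == "expansion":
            params["f1"] = draw(*self.frac_bounds)
            params["r1"] = draw(*self.ratio_bounds)
            params["f2"] = draw(*self.frac_bounds)
            params["r2"] = draw(*self.ratio_bounds)
        return params

    def build(self, params: dict[str, float]) -> coalescent.DemographicModel:
        t_div = params.get("t_div")
        events: list[tuple[float, float]] = []
        if self.family == "expansion":
            anchor = t_div if t_div is not None else 0.0
            events = [
                (params["f1"] * min(anchor, self.event_window), params["r1"]),
                (anchor + params["f2"] * self.event_window, params["r2"]),
            ]
        return coalescent.DemographicModel(
            family=self.family,
            n_samples=self.n_samples,
            theta=params["theta"],
            t_div=t_div,
            growth_rate=params.get("alpha", 0.0),
            expansion_events=events,
            L=self.L,
        )

    def restricted(self, bounds: dict[str, tuple[float, float]]) -> "ModelSpec":
        """Copy of this spec with prior bounds replaced where given."""
        mapping = {
            "theta": "theta_bounds",
            "t_div": "t_div_bounds",
            "alpha": "alpha_bounds",
        }
        kwargs = dict(
            name=self.name,
            family=self.family,
            n_samples=self.n_samples,
            L=self.L,
            theta_bounds=self.theta_bounds,
            t_div_bounds=self.t_div_bounds,
            event_window=self.event_window,
            alpha_bounds=self.alpha_bounds,
            ratio_bounds=self.ratio_bounds,
            frac_bounds=self.frac_bounds,
        )
        for pname, (lo, hi) in bounds.items():
            if pname in mapping:
                kwargs[mapping[pname]] = (max(lo, 1e-6), hi)
            elif pname in {"f1", "f2"}:
                kwargs["frac_bounds"] = (max(lo, 0.0), min(hi, 1.0))
            elif pname in {"r1", "r2"}:
                kwargs["ratio_bounds"] = (max(lo, 1e-6), hi)
        return ModelSpec(**kwargs)


@dataclass
class ReferenceTable:
    """Prior draws: model id + parameters + SuSt per row."""

    model_ids: np.ndarray  # (rows,) str
    params: pd.DataFrame  # rows x union-of-parameters (NaN where absent)
    stats: np.ndarray  # (rows, k)
    stat_names: list[str]
    d_defined: np.ndarray  # (rows,) bool
    seed: int | None = None

    @property
    def n_rows(self) -> int:
        return len(self.model_ids)

    def models(self) -> list[str]:
        return list(dict.fromkeys(self.model_ids.tolist()))


def build_reference_table(
    models: list[ModelSpec],
    n_sims_per_model: int,
    seed: int | np.random.Generator = 0,
) -> ReferenceTable:
    """Simulate ``n_sims_per_model`` draws per model and collect SuSt."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows_stats: list[np.ndarray] = []
    rows_params: list[dict[str, float]] = []
    model_col: list[str] = []
    d_ok: list[bool] = []
    stat_names: list[str] | None = None
    for spec in models:
        for _ in range(n_sims_per_model):
            params = spec.draw_params(rng)
            sim = coalescent.simulate(spec.build(params), rng)
            sust = compute_sust(sim)
            if stat_names is None:
                stat_names = sust.names
            rows_stats.append(sust.values)
            rows_params.append(params)
            model_col.append(spec.name)
            d_ok.append(sust.d_defined)
    return ReferenceTable(
        model_ids=np.array(model_col),
        params=pd.DataFrame(rows_params),
        stats=np.vstack(rows_stats),
        stat_names=stat_names or [],
        d_defined=np.array(d_ok, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------

@dataclass
class AbcResult:
    retained: np.ndarray  # indices into the reference table
    posterior_probabilities: dict[str, float]  # model -> PP on 0-100 scale
    vector: list[str]
    tolerance: float
    distances: np.ndarray  # distance of every reference row
    retained_model_ids: np.ndarray | None = None
    dropped_stats: list[str] = field(default_factory=list)

    def best_model(self) -> str:
        """Model with the highest PP; exact PP ties are broken by the
        smaller mean distance of the tied models' retained rows."""
        pp = self.posterior_probabilities
        top = max(pp.values())
        tied = sorted(m for m, v in pp.items() if v == top)
        if len(tied) == 1 or self.retained_model_ids is None:
            return tied[0]
        d = self.distances[self.retained]
        return min(
            tied,
            key=lambda m: (float(d[self.retained_model_ids == m].mean()), m),
        )


def rejection(
    observed: SuStVector | np.ndarray,
    reference: ReferenceTable,
    tolerance: float = 0.001,
    vector: list[str] | None = None,
) -> AbcResult:
    """Retain the ``tolerance`` fraction of reference rows closest to the
    observed SuSt (Euclidean distance on SD-standardized statistics) and
    report each model's share of the retained set ×100."""
    if not 0 < tolerance <= 1:
        raise AbcError("tolerance must lie in (0, 1]")
    names = vector if vector is not None else list(reference.stat_names)
    unknown = [n for n in names if n not in reference.stat_names]
    if unknown:
        raise AbcError(f"unknown statistics {unknown}")
    cols = [reference.stat_names.index(n) for n in names]
    table = reference.stats[:, cols]
    if isinstance(observed, SuStVector):
        obs = observed.subset(names)
    else:
        arr = np.asarray(observed, dtype=float)
        if arr.shape == (len(reference.stat_names),):
            obs = arr[cols]
        elif arr.shape == (len(names),):
            obs = arr
        else:
            raise AbcError("observed vector length matches neither the table nor the subset")
    sd = table.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if not keep.any():
        raise AbcError("all selected statistics have zero variance")
    z_table = table[:, keep] / sd[keep]
    z_obs = obs[keep] / sd[keep]
    distances = np.sqrt(((z_table - z_obs) ** 2).sum(axis=1))
    n_keep = max(1, math.ceil(tolerance * reference.n_rows))
    retained = np.argsort(distances, kind="stable")[:n_keep]
    kept_models = reference.model_ids[retained]
    pp = {
        m: 100.0 * float(np.sum(kept_models == m)) / n_keep
        for m in reference.models()
    }
    return AbcResult(
        retained=retained,
        posterior_probabilities=pp,
        vector=[n for n, k in zip(names, keep) if k],
        tolerance=tolerance,
        distances=distances,
        retained_model_ids=kept_models,
        dropped_stats=dropped,
    )


# ---------------------------------------------------------------------------
# Summary-statistic vector selection
# ---------------------------------------------------------------------------

def select_vector(
    reference: ReferenceTable,
    n_pods_per_model: int = 10,
    tolerance: float = 0.01,
    seed: int | np.random.Generator = 0,
    candidates: list[str] | None = None,
) -> tuple[list[str], dict[tuple[str, ...], int]]:
    """Choose the SuSt subset that best recovers the true model.

    ``n_pods_per_model`` rows per model are withheld from the reference
    table as pseudo-observed datasets; every subset of ≥2 candidate
    statistics classifies each pod by rejection-PP argmax against the
    remaining rows, and the subset with the most correct classifications
    wins (ties → fewer statistics, then lexicographic order).  Returns
    the winning subset and the per-subset scores.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cand = candidates if candidates is not None else list(reference.stat_names)
    if len(cand) < 2:
        raise AbcError("need at least two candidate statistics")
    pod_idx: list[int] = []
    for m in reference.models():
        rows = np.flatnonzero(reference.model_ids == m)
        if len(rows) <= n_pods_per_model:
            raise AbcError(f"model {m} has too few rows for pod selection")
        pod_idx.extend(rng.choice(rows, size=n_pods_per_model, replace=False))
    pod_idx_arr = np.array(sorted(pod_idx))
    rest = np.setdiff1d(np.arange(reference.n_rows), pod_idx_arr)
    sub_ref = ReferenceTable(
        model_ids=reference.model_ids[rest],
        params=reference.params.iloc[rest].reset_index(drop=True),
        stats=reference.stats[rest],
        stat_names=reference.stat_names,
        d_defined=reference.d_defined[rest],
    )
    scores: dict[tuple[str, ...], int] = {}
    for size in range(2, len(cand) + 1):
        for subset in itertools.combinations(cand, size):
            correct = 0
            for idx in pod_idx_arr:
                obs = SuStVector(reference.stat_names, reference.stats[idx])
                try:
                    res = rejection(obs, sub_ref, tolerance, list(subset))
                except AbcError:
                    continue
                if res.best_model() == reference.model_ids[idx]:
                    correct += 1
            scores[subset] = correct
    best_score = max(scores.values())
    if best_score == 0:
        raise AbcError("models indistinguishable: every subset scored 0")
    winners = [s for s, v in scores.items() if v == best_score]
    winners.sort(key=lambda s: (len(s), s))
    return list(winners[0]), scores


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def gfit(
    observed: SuStVector | np.ndarray,
    reference: ReferenceTable,
    n_components: int = 2,
    vector: list[str] | None = None,
) -> tuple[bool, float]:
    """PCA goodness-of-fit: is the observed SuSt inside the simulated cloud?

    The reference statistics are standardized and projected on their first
    ``n_components`` principal axes; the percentile is the fraction of
    simulated points with smaller Mahalanobis distance from the centroid
    than the observed point.  ``inside`` is percentile ≤ 0.95.
    """
    names = vector if vector is not None else list(reference.stat_names)
    cols = [reference.stat_names.index(n) for n in names]
    table = reference.stats[:, cols]
    obs = observed.subset(names) if isinstance(observed, SuStVector) else (
        np.asarray(observed, dtype=float)
    )
    sd = table.std(axis=0, ddof=0)
    keep = sd > 0
    z = (table[:, keep] - table[:, keep].mean(axis=0)) / sd[keep]
    zo = (obs[keep] - table[:, keep].mean(axis=0)) / sd[keep]
    n_avail = z.shape[1]
    k = min(n_components, n_avail)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    axes = vt[:k]
    scale = s[:k] / math.sqrt(z.shape[0])
    scale = np.where(scale > 0, scale, 1.0)
    proj = z @ axes.T / scale
    proj_obs = zo @ axes.T / scale
    d_ref = (proj**2).sum(axis=1)
    d_obs = float((proj_obs**2).sum())
    percentile = float(np.mean(d_ref < d_obs))
    return percentile <= 0.95, percentile


# ---------------------------------------------------------------------------
# Prior restriction
# ---------------------------------------------------------------------------

def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    if cw[-1] <= 0:
        return float(np.quantile(values, q))
    cw = cw / cw[-1]
    return float(np.interp(q, cw, v))


def restrict_priors(
    result: AbcResult, reference: ReferenceTable
) -> dict[str, tuple[float, float]]:
    """Weighted 2.5%/97.5% interval per parameter over the retained draws.

    Weights are Epanechnikov: w_i = 1 − (d_i/d_max)² with d_max the
    largest retained distance.  When every weight vanishes (all retained
    distances equal) plain empirical percentiles are used.
    """
    if len(result.retained) == 0:
        raise AbcError("empty retained set")
    d = result.distances[result.retained]
    d_max = d.max()
    weights = 1.0 - (d / d_max) ** 2 if d_max > 0 else np.ones_like(d)
    if weights.sum() <= 0:
        weights = np.ones_like(d)
    out: dict[str, tuple[float, float]] = {}
    params = reference.params.iloc[result.retained]
    for col in params.columns:
        vals = params[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        if len(vals[ok]) == 1:
            v = float(vals[ok][0])
            out[col] = (v, v)
            continue
        lo = _weighted_quantile(vals[ok], weights[ok], 0.025)
        hi = _weighted_quantile(vals[ok], weights[ok], 0.975)
        out[col] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# Hierarchical scenario comparison
# ---------------------------------------------------------------------------

def hierarchical_compare(
    finalists: dict[str, ModelSpec],
    n_sims_per_model: int,
    observed: SuStVector,
    tolerance: float = 0.001,
    seed: int | np.random.Generator = 0,
    vector: list[str] | None = None,
) -> AbcResult:
    """Final independent run: the best model of each scenario competes in a
    fresh reference table; PP is reported per scenario."""
    if len(finalists) < 2:
        raise AbcError("need at least two scenarios to compare")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    specs = []
    for scenario, spec in finalists.items():
        specs.append(
            ModelSpec(
                name=scenario,
                family=spec.family,
                n_samples=spec.n_samples,
                L=spec.L,
                theta_bounds=spec.theta_bounds,
                t_div_bounds=spec.t_div_bounds,
                event_window=spec.event_window,
                alpha_bounds=spec.alpha_bounds,
                ratio_bounds=spec.ratio_bounds,
                frac_bounds=spec.frac_bounds,
            )
        )
    table = build_reference_table(specs, n_sims_per_model, rng)
    return rejection(observed, table, tolerance, vector)
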