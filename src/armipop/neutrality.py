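"""Neutrality tests and mismatch-distribution demography.

Tajima's D and Fu's Fs with coalescent-simulation p-values, and the
sudden-expansion (stationarity → growth) model fitted to the mismatch
distribution, with SSD and Harpending's raggedness index assessed by
parametric bootstrap.

The null for both neutrality p-values conditions on the observed sample
size and number of segregating sites (fixed-S coalescent), the convention
of the programs this analysis layer mirrors; a fixed-θ mode is available.
P-values are lower-tailed — the expansion signature is a significantly
*negative* statistic — and carry the (b+1)/(B+1) correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import coalescent
from .data import Alignment
from .diversity import (
    UndefinedStatisticError,
    _pairwise_diff_counts,
    harmonic_number,
    segregating_sites,
)

#: Upper bound for the post-expansion θ1 search (effectively infinite).
THETA1_MAX = 1.0e4


@dataclass
class NeutralityResult:
    D: float
    D_p: float
    Fs: float
    Fs_p: float
    n_sims: int

    @property
    def Fs_degenerate(self) -> bool:
        """True when Fs is the signalled +∞ of a single-haplotype sample."""
        return not math.isfinite(self.Fs)


@dataclass
class MismatchFit:
    """Sudden-expansion fit to an observed mismatch distribution."""

    observed: np.ndarray
    tau_hat: float
    theta0_hat: float
    theta1_hat: float
    tau_ci: tuple[float, float]
    SSD: float
    SSD_p: float
    r: float
    r_p: float
    n_boot: int
    converged: bool = True


# ---------------------------------------------------------------------------
# Core statistics from (n, S, pi, k)
# ---------------------------------------------------------------------------

def tajimas_d_parts(n: int, S: int, pi_locus: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences (per locus).  Raises when undefined (S = 0 or n < 4)."""
    if n < 4:
        raise UndefinedStatisticError(f"Tajima's D needs n >= 4 (n={n})")
    if S < 1:
        raise UndefinedStatisticError("Tajima's D undefined for S = 0")
    a1 = harmonic_number(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_locus - S / a1) / math.sqrt(var)


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 1..n under the Ewens sampling formula.

    K is a sum of independent Bernoulli(θ/(θ+i−1)) indicators (sequential
    "new-type" events), so the distribution is computed by convolution —
    numerically stable for any n without big-integer Stirling numbers.
    """
    if theta <= 0:
        raise UndefinedStatisticError("Ewens distribution needs theta > 0")
    probs = np.zeros(n + 1)
    probs[1] = 1.0  # first draw is always a new type
    for i in range(2, n + 1):
        p_new = theta / (theta + i - 1)
        nxt = probs * (1 - p_new)
        nxt[1:] += probs[:-1] * p_new
        probs = nxt
    return probs[1:]


def fu_fs_parts(n: int, theta_pi: float, k_obs: int) -> float:
    """Fu's Fs = ln(S′/(1−S′)) with S′ = P(K ≥ k_obs | θ̂_π).

    Returns +inf (signalled degenerate) when k_obs = 1, since S′ = 1.
    """
    if k_obs <= 1:
        return math.inf
    if theta_pi <= 0:
        raise UndefinedStatisticError("Fu's Fs needs theta_pi > 0")
    pk = ewens_k_distribution(n, theta_pi)
    s_prime = float(pk[k_obs - 1:].sum())
    s_prime = min(max(s_prime, 1e-300), 1.0)
    if s_prime >= 1.0:
        return math.inf
    return math.log(s_prime / (1.0 - s_prime))


def tajimas_d(aln: Alignment) -> float:
    """Tajima's D of an alignment (complete-deletion sites)."""
    from .diversity import mean_pairwise_differences

    return tajimas_d_parts(
        aln.n, segregating_sites(aln), mean_pairwise_differences(aln)
    )


def fu_fs(aln: Alignment) -> float:
    """Fu's Fs of an alignment: Ewens tail probability at the observed
    haplotype count, with θ estimated by mean pairwise differences."""
    from .data import collapse_haplotypes
    from .diversity import mean_pairwise_differences

    k_obs = collapse_haplotypes(aln, by="all").n_haplotypes
    if k_obs <= 1:
        return math.inf
    return fu_fs_parts(aln.n, mean_pairwise_differences(aln), k_obs)


# -- simulated-sample versions ----------------------------------------------

def _sim_pairwise_mean(sim: coalescent.SimulatedSample) -> float:
    c = sim.genotypes.sum(axis=0).astype(float)
    n = sim.n
    return float(np.sum(c * (n - c)) / (n * (n - 1) / 2.0))


def _sim_k(sim: coalescent.SimulatedSample) -> int:
    return len({row.tobytes() for row in np.ascontiguousarray(sim.genotypes)})


def sim_tajimas_d(sim: coalescent.SimulatedSample) -> float:
    return tajimas_d_parts(sim.n, sim.S, _sim_pairwise_mean(sim))


def sim_fu_fs(sim: coalescent.SimulatedSample) -> float:
    return fu_fs_parts(sim.n, _sim_pairwise_mean(sim), _sim_k(sim))


# ---------------------------------------------------------------------------
# Simulation p-values
# ---------------------------------------------------------------------------

def neutrality_pvalues(
    aln: Alignment,
    n_sims: int = 1000,
    seed: int | np.random.Generator = 0,
    mode: str = "fixed_s",
) -> NeutralityResult:
    """Observed D and Fs with one-tailed (lower) coalescent p-values.

    ``n_sims`` constant-size single-deme genealogies are drawn conditioned
    on the observed n and S (``mode="fixed_s"``) or with θ̂_W mutations
    (``mode="fixed_theta"``); p = (#{simulated ≤ observed} + 1)/(B + 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .diversity import mean_pairwise_differences, watterson_theta

    S = segregating_sites(aln)
    d_obs = tajimas_d(aln)
    fs_obs = fu_fs(aln)
    theta_w = watterson_theta(aln)
    d_le = fs_le = 0
    used = 0
    while used < n_sims:
        if mode == "fixed_s":
            sim = coalescent.simulate_fixed_s(aln.n, S, rng)
        else:
            model = coalescent.DemographicModel(
                family="constant", n_samples=(aln.n,), theta=theta_w
            )
            sim = coalescent.simulate(model, rng)
            if sim.S == 0:
                continue
        used += 1
        if sim_tajimas_d(sim) <= d_obs:
            d_le += 1
        if sim_fu_fs(sim) <= fs_obs:
            fs_le += 1
    return NeutralityResult(
        D=d_obs,
        D_p=(d_le + 1) / (n_sims + 1),
        Fs=fs_obs,
        Fs_p=(fs_le + 1) / (n_sims + 1),
        n_sims=n_sims,
    )


# ---------------------------------------------------------------------------
# Mismatch distribution
# ---------------------------------------------------------------------------

def mismatch_observed(aln: Alignment) -> np.ndarray:
    """Frequencies of pairwise-difference classes 0..d_max (sum to 1)."""
    if aln.n < 2:
        raise UndefinedStatisticError("mismatch distribution needs n >= 2")
    clean = aln.complete_deletion()
    diffs = _pairwise_diff_counts(clean.seqs)
    freqs = np.bincount(diffs).astype(float)
    return freqs / freqs.sum()


def sim_mismatch(sim: coalescent.SimulatedSample) -> np.ndarray:
    diffs = _pairwise_diff_counts(sim.genotypes)
    freqs = np.bincount(diffs).astype(float)
    return freqs / freqs.sum()


def equilibrium_mismatch(theta: float, d_max: int) -> np.ndarray:
    """Stationary mismatch F̂_i(θ) = θ^i/(θ+1)^{i+1}, i = 0..d_max.

    Evaluated in log space so long class ranges cannot overflow.
    """
    i = np.arange(d_max + 1)
    if theta == 0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    return np.exp(i * math.log(theta) - (i + 1) * math.log(theta + 1.0))


def mismatch_expected(
    tau: float, theta0: float, theta1: float, d_max: int
) -> np.ndarray:
    """Sudden-expansion mismatch distribution (Rogers–Harpending).

    F_i = F̂_i(θ1) + e^{−τ(θ1+1)/θ1} Σ_{j=0}^{i} (τ^j/j!) [F̂_{i−j}(θ0) −
    F̂_{i−j}(θ1)] for a population at mutation-scaled size θ0 that jumped
    to θ1 at mutational time τ before the present.
    """
    if theta0 <= 0 or theta1 <= 0:
        raise ValueError("theta0 and theta1 must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    f0 = equilibrium_mismatch(theta0, d_max)
    f1 = equilibrium_mismatch(theta1, d_max)
    if tau == 0:
        return f0.copy()
    # Poisson(τ) weights for j = 0..d_max, built in log space for large τ
    j = np.arange(d_max + 1)
    log_w = j * math.log(tau) - tau - np.cumsum(
        np.concatenate(([0.0], np.log(np.maximum(j[1:], 1))))
    )
    w = np.exp(log_w)
    diff = f0 - f1
    conv = np.array([np.sum(w[: i + 1] * diff[i::-1]) for i in range(d_max + 1)])
    damp = math.exp(-tau / theta1) if theta1 > 0 else 0.0
    # e^{−τ(θ1+1)/θ1} = e^{−τ} · e^{−τ/θ1}; the e^{−τ} is inside the
    # Poisson weights already, so only the extra e^{−τ/θ1} remains.
    return f1 + damp * conv


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness r = Σ_{i=1}^{d+1} (x_i − x_{i−1})²,
    with x_{d+1} = 0 appended past the last observed class."""
    x = np.concatenate([np.asarray(freqs, dtype=float), [0.0]])
    return float(np.sum(np.diff(x) ** 2))


def _ssd(params: np.ndarray, observed: np.ndarray) -> float:
    tau, theta0, theta1 = params
    if tau < 0 or theta0 <= 0 or theta1 <= 0:
        return math.inf
    exp = mismatch_expected(tau, theta0, theta1, len(observed) - 1)
    return float(np.sum((observed - exp) ** 2))


def _fit_params(observed: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Coarse grid then bounded Nelder–Mead refinement of (τ, θ0, θ1)."""
    d = len(observed) - 1
    tau_grid = np.linspace(0.0, max(2.0 * (d + 1), 4.0), 13)
    theta0_grid = np.array([0.01, 0.1, 0.5, 1.0, 2.0, 5.0])
    theta1_grid = np.array([1.0, 10.0, 100.0, 1000.0, THETA1_MAX])
    best, best_ssd = None, math.inf
    for t in tau_grid:
        for t0 in theta0_grid:
            for t1 in theta1_grid:
                s = _ssd(np.array([t, t0, t1]), observed)
                if s < best_ssd:
                    best, best_ssd = np.array([t, t0, t1]), s
    res = optimize.minimize(
        _ssd,
        best,
        args=(observed,),
        method="Nelder-Mead",
        bounds=[(0.0, 4.0 * (d + 1)), (1e-6, 100.0), (1e-6, THETA1_MAX)],
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    if res.fun <= best_ssd:
        return res.x, float(res.fun), bool(res.success)
    return best, best_ssd, True


def fit_sudden_expansion(
    observed: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
    n_boot: int = 1000,
) -> MismatchFit:
    """Fit the sudden-expansion model to an observed mismatch distribution.

    Point estimates minimize SSD between observed and model frequencies.
    Significance of SSD and of the raggedness index, and the 95% interval
    for τ, come from a parametric bootstrap: coalescent samples of size
    ``n`` are simulated under the fitted expansion, their mismatch refit,
    and p = (#{boot ≥ observed} + 1)/(B + 1).
    """
    observed = np.asarray(observed, dtype=float)
    if observed.ndim != 1 or observed.size == 0 or abs(observed.sum() - 1) > 1e-8:
        raise ValueError("observed must be a frequency vector summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params, ssd_obs, converged = _fit_params(observed)
    tau_hat, theta0_hat, theta1_hat = (float(v) for v in params)
    r_obs = raggedness(observed)

    # parametric bootstrap under the fitted model; mutational age tau =
    # 2*u*t maps to t/(2N) = tau/theta1 on the simulator's time scale
    t_event = tau_hat / theta1_hat if theta1_hat > 0 else 0.0
    model = coalescent.DemographicModel(
        family="expansion",
        n_samples=(n,),
        theta=theta1_hat,
        expansion_events=[(t_event, max(theta0_hat / theta1_hat, 1e-9))],
    )
    ssd_ge = r_ge = 0
    taus = []
    for _ in range(n_boot):
        sim = coalescent.simulate(model, rng)
        freqs = sim_mismatch(sim)
        boot_params, boot_ssd, _ = _fit_params(freqs)
        taus.append(boot_params[0])
        if boot_ssd >= ssd_obs:
            ssd_ge += 1
        if raggedness(freqs) >= r_obs:
            r_ge += 1
    if n_boot > 0:
        lo, hi = np.percentile(taus, [2.5, 97.5])
        ssd_p = (ssd_ge + 1) / (n_boot + 1)
        r_p = (r_ge + 1) / (n_boot + 1)
    else:
        lo = hi = tau_hat
        ssd_p = r_p = float("nan")
    return MismatchFit(
        observed=observed,
        tau_hat=tau_hat,
        theta0_hat=theta0_hat,
        theta1_hat=theta1_hat,
        tau_ci=(float(lo), float(hi)),
        SSD=ssd_obs,
        SSD_p=ssd_p,
        r=r_obs,
        r_p=r_p,
        n_boot=n_boot,
        converged=converged,
    )
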