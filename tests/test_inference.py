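"""Rejection-ABC pipeline: summary statistics, rejection properties,
vector selection, goodness of fit, prior restriction, hierarchy."""

import itertools

import numpy as np
import pandas as pd
import pytest

from armipop.coalescent import SimulatedSample
from armipop.data import Alignment
from armipop.inference import (
    AbcError,
    ModelSpec,
    ReferenceTable,
    SuStVector,
    build_reference_table,
    compute_sust,
    gfit,
    hierarchical_compare,
    rejection,
    restrict_priors,
    select_vector,
)


def make_sample(geno, demes, L=100):
    geno = np.asarray(geno, dtype=np.int8)
    return SimulatedSample(
        genotypes=geno,
        positions=np.linspace(0.1, 0.9, geno.shape[1]),
        demes=np.asarray(demes),
        tree_height=1.0,
        total_branch_length=2.0,
        L=L,
    )


def make_table(stats, models, params=None):
    stats = np.asarray(stats, dtype=float)
    return ReferenceTable(
        model_ids=np.asarray(models),
        params=params if params is not None else pd.DataFrame(
            {"theta": np.arange(len(models), dtype=float)}
        ),
        stats=stats,
        stat_names=[f"s{i}" for i in range(stats.shape[1])],
        d_defined=np.ones(len(models), dtype=bool),
    )


class TestComputeSust:
    def test_identical_demes_equalise_within_and_between(self):
        geno = [[0, 1], [1, 0], [0, 1], [1, 0]]
        sust = compute_sust(make_sample(geno, [0, 0, 1, 1]))
        s = sust.as_series()
        assert s["pi_w_1"] == pytest.approx(s["pi_w_2"])
        assert s["pi_b_1_2"] == pytest.approx(s["pi"], rel=0.5)

    def test_monomorphic_flags_undefined_d(self):
        sust = compute_sust(make_sample(np.zeros((4, 0)), [0, 0, 1, 1]))
        assert not sust.d_defined
        assert sust.as_series()["D"] == 0.0
        assert sust.as_series()["SS"] == 0.0

    def test_matches_brute_force_on_toy_alignment(self):
        seqs = ["AAAA", "AAAT", "AATT", "ATTT", "TTTT", "AAAA"]
        pops = ["d1", "d1", "d1", "d2", "d2", "d2"]
        aln = Alignment.from_strings(
            [f"i{k}" for k in range(6)], seqs, pops, pops
        )
        sust = compute_sust(aln).as_series()
        L = 4

        def pdist(a, b):
            return sum(x != y for x, y in zip(a, b))

        pairs = list(itertools.combinations(range(6), 2))
        pi = np.mean([pdist(seqs[i], seqs[j]) for i, j in pairs]) / L
        within1 = np.mean([pdist(seqs[i], seqs[j])
                           for i, j in pairs if i < 3 and j < 3]) / L
        between = np.mean([pdist(seqs[i], seqs[j])
                           for i in range(3) for j in range(3, 6)]) / L
        assert sust["pi"] == pytest.approx(pi)
        assert sust["pi_w_1"] == pytest.approx(within1)
        assert sust["pi_b_1_2"] == pytest.approx(between)
        assert sust["SS"] == 4

    def test_singleton_deme_flagged_nan(self):
        sust = compute_sust(make_sample([[1], [0], [0]], [0, 1, 1]))
        assert np.isnan(sust.as_series()["pi_w_1"])


class TestRejection:
    def test_pp_sums_to_100_and_exact_match_wins(self):
        stats = [[0.0, 0.0], [5.0, 5.0], [9.0, 1.0], [1.0, 9.0]]
        table = make_table(stats, ["a", "b", "c", "d"])
        res = rejection(np.array([5.0, 5.0]), table, tolerance=0.25)
        assert res.posterior_probabilities["b"] == 100.0
        assert sum(res.posterior_probabilities.values()) == pytest.approx(100.0)

    def test_tolerance_one_recovers_prior_shares(self):
        stats = np.random.default_rng(0).normal(size=(90, 3))
        models = ["m1"] * 30 + ["m2"] * 30 + ["m3"] * 30
        table = make_table(stats, models)
        res = rejection(np.zeros(3), table, tolerance=1.0)
        for m in ("m1", "m2", "m3"):
            assert res.posterior_probabilities[m] == pytest.approx(100 / 3)

    def test_invariant_to_duplicating_reference_rows(self):
        rng = np.random.default_rng(1)
        stats = rng.normal(size=(60, 3))
        models = ["m1"] * 20 + ["m2"] * 20 + ["m3"] * 20
        obs = rng.normal(size=3)
        t1 = make_table(stats, models)
        t2 = make_table(
            np.vstack([stats, stats]), models + models,
            params=pd.DataFrame({"theta": np.zeros(120)}),
        )
        r1 = rejection(obs, t1, tolerance=0.1)
        r2 = rejection(obs, t2, tolerance=0.1)
        assert r1.posterior_probabilities == pytest.approx(
            r2.posterior_probabilities
        )

    def test_zero_variance_stat_dropped_with_warning_record(self):
        stats = [[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]]
        table = make_table(stats, ["a", "b", "c"])
        res = rejection(np.array([2.0, 7.0]), table, tolerance=0.4)
        assert res.dropped_stats == ["s1"]

    def test_bad_tolerance_rejected(self):
        table = make_table([[1.0, 2.0]], ["a"])
        with pytest.raises(AbcError):
            rejection(np.array([1.0, 2.0]), table, tolerance=0.0)


class TestSelectVector:
    def test_planted_informative_stat_always_included(self):
        # models differ only in s1; every winning subset must contain it
        rng = np.random.default_rng(3)
        n = 300
        s_noise = rng.normal(size=(2 * n, 2))
        s_signal = np.concatenate([np.zeros(n), 8 + np.zeros(n)])
        s_signal = s_signal + rng.normal(scale=0.3, size=2 * n)
        stats = np.column_stack([s_noise[:, 0], s_signal, s_noise[:, 1]])
        table = make_table(stats, ["a"] * n + ["b"] * n,
                           params=pd.DataFrame({"theta": np.zeros(2 * n)}))
        vec, scores = select_vector(table, n_pods_per_model=10,
                                    tolerance=0.05, seed=0)
        assert "s1" in vec
        with_s1 = max(v for s, v in scores.items() if "s1" in s)
        without_s1 = max(v for s, v in scores.items() if "s1" not in s)
        assert with_s1 > without_s1

    def test_single_candidate_rejected(self):
        table = make_table(np.random.default_rng(0).normal(size=(40, 2)),
                           ["a"] * 20 + ["b"] * 20)
        with pytest.raises(AbcError):
            select_vector(table, candidates=["s0"], seed=0)

    def test_tie_break_prefers_fewer_stats(self):
        rng = np.random.default_rng(5)
        n = 200
        sig = np.concatenate([np.zeros(n), 10 + np.zeros(n)]) + rng.normal(
            scale=0.1, size=2 * n
        )
        stats = np.column_stack([sig, sig + rng.normal(scale=0.01, size=2 * n)])
        table = make_table(stats, ["a"] * n + ["b"] * n,
                           params=pd.DataFrame({"theta": np.zeros(2 * n)}))
        vec, scores = select_vector(table, n_pods_per_model=8,
                                    tolerance=0.05, seed=1)
        assert len(vec) == 2  # both subsets perfect; the only size-2 wins


class TestGfit:
    def test_centroid_is_inside(self):
        rng = np.random.default_rng(2)
        stats = rng.normal(size=(500, 4))
        table = make_table(stats, ["m"] * 500,
                           params=pd.DataFrame({"theta": np.zeros(500)}))
        inside, pct = gfit(stats.mean(axis=0), table)
        assert inside and pct < 0.1

    def test_far_outlier_is_outside(self):
        rng = np.random.default_rng(2)
        stats = rng.normal(size=(500, 4))
        table = make_table(stats, ["m"] * 500,
                           params=pd.DataFrame({"theta": np.zeros(500)}))
        inside, pct = gfit(stats.mean(axis=0) + 10 * stats.std(axis=0), table)
        assert not inside and pct > 0.95

    def test_reference_pods_percentile_uniform(self):
        rng = np.random.default_rng(4)
        stats = rng.normal(size=(2000, 3))
        table = make_table(stats, ["m"] * 2000,
                           params=pd.DataFrame({"theta": np.zeros(2000)}))
        pct = np.array([gfit(stats[i], table)[1] for i in range(200)])
        from scipy import stats as sps

        assert sps.kstest(pct, "uniform").pvalue > 0.01


class TestRestrictPriors:
    def _result(self, distances, retained, models):
        return_table = make_table(
            np.zeros((len(models), 2)), models,
            params=pd.DataFrame({"theta": np.linspace(0, 1, len(models))}),
        )
        from armipop.inference import AbcResult

        res = AbcResult(
            retained=np.asarray(retained),
            posterior_probabilities={"m": 100.0},
            vector=["s0", "s1"],
            tolerance=0.1,
            distances=np.asarray(distances, dtype=float),
            retained_model_ids=np.asarray(models)[retained],
        )
        return res, return_table

    def test_equal_distances_give_plain_percentiles(self):
        n = 200
        res, table = self._result(
            np.ones(n), np.arange(n), ["m"] * n
        )
        bounds = restrict_priors(res, table)
        vals = table.params["theta"].to_numpy()
        lo, hi = bounds["theta"]
        assert lo == pytest.approx(np.quantile(vals, 0.025), abs=0.02)
        assert hi == pytest.approx(np.quantile(vals, 0.975), abs=0.02)

    def test_single_point_degenerates(self):
        res, table = self._result([0.5, 0.9], [0], ["m", "m"])
        bounds = restrict_priors(res, table)
        assert bounds["theta"][0] == bounds["theta"][1]

    def test_posterior_interval_covers_generating_theta(self, rng):
        # concentrated retained set around the true value
        true_theta = 2.0
        draws = true_theta + rng.normal(scale=0.1, size=100)
        table = make_table(
            np.zeros((100, 2)), ["m"] * 100,
            params=pd.DataFrame({"theta": draws}),
        )
        from armipop.inference import AbcResult

        res = AbcResult(
            retained=np.arange(100),
            posterior_probabilities={"m": 100.0},
            vector=["s0"],
            tolerance=1.0,
            distances=np.abs(draws - true_theta),
            retained_model_ids=np.array(["m"] * 100),
        )
        lo, hi = restrict_priors(res, table)["theta"]
        assert lo < true_theta < hi


class TestEndToEnd:
    def test_reference_table_shape_and_determinism(self):
        models = [
            ModelSpec(name="a", family="constant", n_samples=(6, 6), L=200),
            ModelSpec(name="c", family="expansion", n_samples=(6, 6), L=200),
        ]
        t1 = build_reference_table(models, 15, seed=11)
        t2 = build_reference_table(models, 15, seed=11)
        assert t1.n_rows == 30
        assert (t1.model_ids == "a").sum() == 15
        assert np.array_equal(t1.stats, t2.stats)
        assert t1.params.equals(t2.params)

    def test_theta_prior_bound_respected(self):
        spec = ModelSpec(name="a", family="constant", n_samples=(4, 4))
        rng = np.random.default_rng(0)
        draws = [spec.draw_params(rng)["theta"] for _ in range(500)]
        assert 0 < min(draws) and max(draws) <= 4.123

    def test_hierarchical_pp_sums_and_identical_finalists_near_uniform(self):
        finalists = {
            "scenario1": ModelSpec(name="x", family="constant", n_samples=(5, 5), L=200),
            "scenario2": ModelSpec(name="y", family="constant", n_samples=(5, 5), L=200),
        }
        obs_spec = ModelSpec(name="obs", family="constant", n_samples=(5, 5), L=200)
        rng = np.random.default_rng(9)
        from armipop import coalescent

        sim = coalescent.simulate(obs_spec.build(obs_spec.draw_params(rng)), rng)
        res = hierarchical_compare(
            finalists, n_sims_per_model=400, observed=compute_sust(sim),
            tolerance=0.1, seed=21,
        )
        pp = res.posterior_probabilities
        assert sum(pp.values()) == pytest.approx(100.0)
        assert abs(pp["scenario1"] - pp["scenario2"]) < 40  # near-uniform

    def test_restricted_spec_carries_new_bounds(self):
        spec = ModelSpec(name="c", family="expansion")
        new = spec.restricted({"theta": (1.0, 2.0), "t_div": (0.2, 0.4)})
        assert new.theta_bounds == (1.0, 2.0)
        assert new.t_div_bounds == (0.2, 0.4)
        assert new.ratio_bounds == spec.ratio_bounds
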