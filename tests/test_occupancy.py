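"""Clustering feasibility model: exact solvers, MC estimator, sweeps.

Independent oracles: direct binomial pmf summation for the per-branch tail
and exhaustive B^N enumeration for the any-branch (maximum occupancy)
probability.
"""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

from pcxltp.occupancy import (
    ConnectivityParams,
    SynapticClusteringModel,
    allocate_to_branches,
    estimate_clustering_mc,
    prob_any_branch_clustered_exact,
    prob_branch_clustered_exact,
    sample_synapse_count,
    sweep_clustering,
    synapse_count_pmf,
)

FIXED = ConnectivityParams(synapse_count_model="fixed")


def enum_any_branch(n: int, n_branches: int, k: int) -> float:
    """Oracle: exhaustive enumeration of all B^N equally likely assignments."""
    if n == 0:
        return 0.0 if k >= 1 else 1.0
    hits = 0
    for assign in itertools.product(range(n_branches), repeat=n):
        counts = [assign.count(b) for b in range(n_branches)]
        if max(counts) >= k:
            hits += 1
    return hits / n_branches**n


def tail_by_pmf_summation(n: int, p: float, k: int) -> float:
    """Oracle: direct summation of the binomial pmf from k to n."""
    return float(sum(sps.binom.pmf(j, n, p) for j in range(k, n + 1)))


class TestParams:
    def test_defaults_reproduce_feasibility_arithmetic(self):
        p = ConnectivityParams()
        assert p.expected_synapses == pytest.approx(70.4)
        assert p.fixed_synapse_count == 70
        assert p.spines_per_branch_band >= 100

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_glomeruli=-1),
            dict(mean_syn_per_glom=-0.1),
            dict(synapse_count_model="gamma"),
            dict(synapse_count_model="bernoulli_per_glomerulus", mean_syn_per_glom=1.5),
            dict(n_branches=0),
            dict(nmda_threshold=0),
            dict(branch_weights=(0.5, 0.6), n_branches=2),
            dict(spine_capacity=5),  # below threshold 10
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ConnectivityParams(**kwargs)


class TestSynapseCount:
    def test_fixed_model_gives_70(self, rng):
        assert sample_synapse_count(FIXED, rng) == 70

    @pytest.mark.parametrize("model", ["fixed", "bernoulli_per_glomerulus", "poisson"])
    def test_zero_mean_gives_zero(self, model, rng):
        p = ConnectivityParams(mean_syn_per_glom=0.0, synapse_count_model=model)
        assert sample_synapse_count(p, rng) == 0

    def test_bernoulli_sample_mean_matches_closed_form(self, rng):
        p = ConnectivityParams()
        draws = np.array([sample_synapse_count(p, rng) for _ in range(10_000)])
        se = math.sqrt(110 * 0.64 * 0.36 / len(draws))
        assert abs(draws.mean() - 70.4) < 3 * se


class TestAllocation:
    def test_zero_synapses_all_zero(self, rng):
        s = allocate_to_branches(0, FIXED, rng)
        assert s.total == 0 and np.all(s.counts == 0)

    def test_counts_conserved(self, rng):
        for n in (1, 7, 70, 500):
            s = allocate_to_branches(n, FIXED, rng)
            assert int(s.counts.sum()) == n

    def test_uniform_allocation_mean(self, rng):
        n_draws = 20_000
        counts = np.stack(
            [allocate_to_branches(70, FIXED, rng).counts for _ in range(n_draws)]
        )
        # multinomial per-branch mean N/B with binomial variance
        se = math.sqrt(70 * 0.1 * 0.9 / n_draws)
        assert np.all(np.abs(counts.mean(axis=0) - 7.0) < 4 * se)

    def test_capacity_respected_and_conserved(self, rng):
        p = replace(FIXED, spine_capacity=10)
        for _ in range(50):
            s = allocate_to_branches(70, p, rng)
            assert int(s.counts.sum()) == 70
            assert np.all(s.counts <= 10)

    def test_infeasible_capacity_errors(self, rng):
        p = replace(FIXED, spine_capacity=10)
        with pytest.raises(ValueError, match="capacity"):
            allocate_to_branches(101, p, rng)


class TestPerBranchExact:
    def test_fixed_70_matches_pmf_summation_oracle(self):
        expected = tail_by_pmf_summation(70, 0.1, 10)
        assert expected == pytest.approx(0.1585573, abs=5e-8)
        assert prob_branch_clustered_exact(FIXED) == pytest.approx(expected, abs=1e-12)

    def test_threshold_zero_case_and_overflow(self):
        # k exceeding the total gives probability 0
        assert prob_branch_clustered_exact(replace(FIXED, nmda_threshold=71)) == 0.0

    def test_bernoulli_model_equals_thinning_and_mixture(self):
        p = ConnectivityParams()  # bernoulli default
        val = prob_branch_clustered_exact(p)
        assert val == pytest.approx(float(sps.binom.sf(9, 110, 0.064)), abs=1e-12)
        ns, pmf = synapse_count_pmf(p)
        mixture = float(sum(w * tail_by_pmf_summation(int(n), 0.1, 10) for n, w in zip(ns, pmf)))
        assert val == pytest.approx(mixture, abs=1e-10)

    def test_poisson_model_is_thinned_poisson_tail(self):
        p = ConnectivityParams(synapse_count_model="poisson")
        assert prob_branch_clustered_exact(p) == pytest.approx(
            float(sps.poisson.sf(9, 7.04)), abs=1e-12
        )

    def test_cap_unsupported(self):
        with pytest.raises(ValueError, match="cap"):
            prob_branch_clustered_exact(replace(FIXED, spine_capacity=50))


class TestAnyBranchExact:
    def test_two_branches_four_synapses(self):
        p = ConnectivityParams(
            n_glomeruli=4, mean_syn_per_glom=1.0, synapse_count_model="fixed",
            n_branches=2, nmda_threshold=3,
        )
        assert prob_any_branch_clustered_exact(p) == pytest.approx(0.625, abs=1e-12)
        assert enum_any_branch(4, 2, 3) == 0.625

    def test_threshold_one_is_certain(self):
        p = replace(FIXED, nmda_threshold=1)
        assert prob_any_branch_clustered_exact(p) == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_exhaustively(self):
        """DP solver equals full B^N enumeration for all N<=8, B<=4, all k."""
        for B in (2, 3, 4):
            for N in range(0, 9):
                expected_by_k = {k: enum_any_branch(N, B, k) for k in range(1, N + 2)}
                for k, expected in expected_by_k.items():
                    p = ConnectivityParams(
                        n_glomeruli=max(N, 1),
                        mean_syn_per_glom=N / max(N, 1),
                        synapse_count_model="fixed",
                        n_branches=B,
                        nmda_threshold=k,
                    )
                    got = prob_any_branch_clustered_exact(p)
                    assert got == pytest.approx(expected, abs=1e-10), (B, N, k)

    def test_single_branch_reduces_to_count_tail(self):
        # with B = 1 both probabilities equal the synapse-count tail at k
        for model in ("fixed", "bernoulli_per_glomerulus", "poisson"):
            p = ConnectivityParams(
                synapse_count_model=model, n_branches=1, nmda_threshold=65
            )
            per = prob_branch_clustered_exact(p)
            any_ = prob_any_branch_clustered_exact(p)
            ns, pmf = synapse_count_pmf(p)
            tail = float(pmf[ns >= 65].sum())
            assert per == pytest.approx(tail, abs=1e-9)
            assert any_ == pytest.approx(tail, abs=1e-9)

    def test_default_fixed_value_frozen(self):
        # frozen against the enumeration-validated DP at full scale and MC
        assert prob_any_branch_clustered_exact(FIXED) == pytest.approx(
            0.9162488, abs=1e-6
        )

    def test_too_large_suggests_mc(self):
        p = ConnectivityParams(
            n_glomeruli=10_000, mean_syn_per_glom=1.0,
            synapse_count_model="fixed", nmda_threshold=10,
        )
        with pytest.raises(ValueError, match="[Mm]onte|mc|large"):
            prob_any_branch_clustered_exact(p, max_exact_n=5000)


class TestMonteCarlo:
    def test_matches_exact_within_4_se(self):
        res = estimate_clustering_mc(FIXED, n_neurons=200_000, seed=7)
        assert abs(res.p_per_branch - 0.1585573) < 4 * res.mc_se_per_branch
        assert abs(res.p_any_branch - 0.9162488) < 4 * res.mc_se_any_branch

    def test_threshold_zero_not_allowed_but_one_with_n_certain(self):
        p = replace(FIXED, nmda_threshold=1)
        res = estimate_clustering_mc(p, n_neurons=1000, seed=0)
        assert res.p_per_branch > 0
        assert res.p_any_branch == 1.0

    def test_reproducible_under_seed(self):
        a = estimate_clustering_mc(FIXED, n_neurons=5000, seed=42)
        b = estimate_clustering_mc(FIXED, n_neurons=5000, seed=42)
        assert a.p_per_branch == b.p_per_branch
        assert a.p_any_branch == b.p_any_branch

    def test_probability_ordering_invariants(self):
        for seed in range(3):
            res = estimate_clustering_mc(FIXED, n_neurons=20_000, seed=seed)
            assert 0.0 <= res.p_per_branch <= res.p_any_branch <= 1.0
            assert res.p_any_branch <= 10 * res.p_per_branch + 4 * (
                res.mc_se_any_branch + 10 * res.mc_se_per_branch
            )

    def test_branches_exchangeable_under_uniform_weights(self, rng):
        # designated-branch hit rate should not depend on the branch index
        counts = rng.multinomial(70, [0.1] * 10, size=50_000)
        hits = (counts >= 10).mean(axis=0)
        se = math.sqrt(0.16 * 0.84 / 50_000)
        assert np.all(np.abs(hits - hits.mean()) < 5 * se)

    def test_capped_mc_runs(self):
        p = replace(FIXED, spine_capacity=12)
        res = estimate_clustering_mc(p, n_neurons=500, seed=1)
        assert 0 <= res.p_per_branch <= res.p_any_branch <= 1


class TestSweep:
    def test_monotone_in_threshold_and_n(self):
        df_k = sweep_clustering(
            FIXED, {"nmda_threshold": list(range(5, 16))}, method="exact"
        )
        assert np.all(np.diff(df_k["p_per_branch"]) <= 1e-12)
        assert np.all(np.diff(df_k["p_any_branch"]) <= 1e-12)
        df_n = sweep_clustering(
            FIXED,
            {"n_glomeruli": [40, 70, 100], "mean_syn_per_glom": [1.0]},
            method="exact",
        )
        assert np.all(np.diff(df_n["p_per_branch"]) >= -1e-12)

    def test_empty_grid_is_point_evaluation(self):
        df = sweep_clustering(FIXED, {}, method="exact")
        assert len(df) == 1
        assert df.loc[0, "p_per_branch"] == pytest.approx(0.1585573, abs=1e-6)

    def test_unknown_field_lists_valid_names(self):
        with pytest.raises(ValueError, match="nmda_threshold"):
            sweep_clustering(FIXED, {"threshold": [5]})


class TestModelObject:
    def test_exact_fit_and_summary(self):
        res = SynapticClusteringModel(FIXED).fit()
        assert res.method == "exact"
        text = res.summary()
        assert "0.1586" in text and "0.9162" in text

    def test_both_carries_exact_crosscheck(self):
        res = SynapticClusteringModel(FIXED).fit(method="both", n_neurons=50_000, seed=3)
        assert abs(res.p_per_branch - res.exact.p_per_branch) < 5 * res.mc_se_per_branch
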