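import math

import numpy as np
import pytest

from caenophylo.ancestral import (
    MkModel,
    fit_er_rate,
    marginal_posteriors,
    mk_loglik,
    sample_stochastic_maps,
    summarize_maps,
)
from caenophylo.synth import sim_discrete_character, sim_species_tree
from caenophylo.trees import parse_newick

from conftest import brute_force_loglik, brute_force_marginals, random_rooted_tree


class TestMkLoglik:
    def test_zero_rate_monomorphic_is_log_prior(self):
        t = parse_newick("(A:1,B:1);")
        assert mk_loglik(t, {"A": 0, "B": 0}, MkModel(2, 0.0)) == pytest.approx(
            math.log(0.5)
        )

    def test_zero_rate_polymorphic_is_impossible(self):
        t = parse_newick("(A:1,B:1);")
        assert mk_loglik(t, {"A": 0, "B": 1}, MkModel(2, 0.0)) == float("-inf")

    def test_missing_leaf_state_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            mk_loglik(t, {"A": 0}, MkModel(2, 1.0))

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_enumeration_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        tree = random_rooted_tree(rng, n)
        char = {l.label: int(rng.integers(k)) for l in tree.leaves()}
        model = MkModel(k, float(rng.uniform(0.1, 2.0)))
        assert mk_loglik(tree, char, model) == pytest.approx(
            brute_force_loglik(tree, char, model), abs=1e-10
        )

    def test_rate_time_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        tree = random_rooted_tree(rng, 6)
        char = {l.label: int(rng.integers(2)) for l in tree.leaves()}
        base = mk_loglik(tree, char, MkModel(2, 0.8))
        scaled = tree.copy()
        for node in scaled.preorder():
            if node.length is not None:
                node.length *= 4.0
        assert mk_loglik(scaled, char, MkModel(2, 0.2)) == pytest.approx(
            base, abs=1e-8
        )


class TestFitERRate:
    def test_monomorphic_character_boundary_zero(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        fit = fit_er_rate(t, {"A": 1, "B": 1, "C": 1})
        assert fit.alpha == 0.0 and fit.boundary

    def test_recovers_simulated_rate(self):
        # median over replicates of trees large enough to be informative
        estimates = []
        for seed in range(40):
            tree, _ = sim_species_tree(100, 25.0, seed=seed)
            tips, _, _ = sim_discrete_character(tree, 1.0, 2, seed=seed + 1000)
            if len(set(tips.values())) < 2:
                continue
            estimates.append(fit_er_rate(tree, tips, alpha_max=50.0).alpha)
        med = float(np.median(estimates))
        assert 0.5 <= med <= 2.0

    def test_fitted_maximum_beats_neighbours(self):
        rng = np.random.default_rng(1)
        tree = random_rooted_tree(rng, 12)
        char = {l.label: int(rng.integers(2)) for l in tree.leaves()}
        fit = fit_er_rate(tree, char)
        if not fit.boundary:
            for factor in (0.9, 1.1):
                assert fit.loglik >= mk_loglik(
                    tree, char, MkModel(2, fit.alpha * factor)
                ) - 1e-9


class TestMarginalPosteriors:
    def test_zero_rate_monomorphic_certain(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        char = {x: 1 for x in "ABCD"}
        post = marginal_posteriors(t, char, MkModel(2, 0.0))
        for clade, p in post.probs.items():
            assert p == pytest.approx([0.0, 1.0])

    def test_symmetric_split_gives_half_half_root(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        post = marginal_posteriors(
            t, {"A": 0, "B": 0, "C": 1, "D": 1}, MkModel(2, 0.6)
        )
        assert post[frozenset("ABCD")] == pytest.approx([0.5, 0.5])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_rooted_tree(rng, 5)
        char = {l.label: int(rng.integers(2)) for l in tree.leaves()}
        model = MkModel(2, 0.9)
        post = marginal_posteriors(tree, char, model)
        oracle = brute_force_marginals(tree, char, model)
        for clade, expected in oracle.items():
            assert np.abs(post[clade] - expected).max() < 1e-10


class TestStochasticMaps:
    def test_monomorphic_zero_rate_constant_maps(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        char = {"A": 1, "B": 1, "C": 1}
        maps = sample_stochastic_maps(t, char, MkModel(2, 0.0), n_maps=10, seed=0)
        assert all(m.n_transitions() == 0 for m in maps.maps)
        assert all(set(m.node_states.values()) == {1} for m in maps.maps)

    def test_zero_rate_polymorphic_infeasible(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            sample_stochastic_maps(t, {"A": 0, "B": 1}, MkModel(2, 0.0), 5, 0)

    def test_segment_invariants_hold(self):
        rng = np.random.default_rng(3)
        tree = random_rooted_tree(rng, 6)
        char = {l.label: int(rng.integers(2)) for l in tree.leaves()}
        maps = sample_stochastic_maps(tree, char, MkModel(2, 1.2), n_maps=50, seed=1)
        lengths = {tree.leaf_set(n): n.length or 0.0
                   for n in tree.preorder() if n is not tree.root}
        tip_state = {frozenset({lab}): s for lab, s in char.items()}
        for m in maps.maps:
            for clade, segs in m.branch_segments.items():
                assert sum(d for _, d in segs) == pytest.approx(lengths[clade], abs=1e-9)
                for (s1, _), (s2, _) in zip(segs[:-1], segs[1:]):
                    assert s1 != s2
                if clade in tip_state:
                    assert segs[-1][0] == tip_state[clade]
            assert m.dwell_times(2).sum() == pytest.approx(
                tree.total_length(), abs=1e-9
            )

    def test_node_frequencies_match_exact_marginals(self):
        tree, _ = sim_species_tree(6, 1.0, seed=2)
        tips, _, _ = sim_discrete_character(tree, 0.8, 2, seed=3)
        if len(set(tips.values())) < 2:
            tips[sorted(tips)[0]] = 1 - tips[sorted(tips)[0]]
        model = MkModel(2, 1.0)
        maps = sample_stochastic_maps(tree, tips, model, n_maps=1000, seed=4)
        freq = summarize_maps(maps).posterior
        exact = marginal_posteriors(tree, tips, model)
        for clade in exact.probs:
            assert np.abs(freq[clade] - exact[clade]).max() < 0.05

    def test_deterministic_under_seed(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        char = {"A": 0, "B": 1, "C": 1}
        a = sample_stochastic_maps(t, char, MkModel(2, 1.0), n_maps=20, seed=9)
        b = sample_stochastic_maps(t, char, MkModel(2, 1.0), n_maps=20, seed=9)
        for ma, mb in zip(a.maps, b.maps):
            assert ma.node_states == mb.node_states
            assert ma.branch_segments == mb.branch_segments

    def test_branch_transition_count_matches_conditioned_expectation(self):
        # single branch of length 1, endpoints fixed 0 -> 1, alpha = 1, k = 2:
        # E[N] = sum_n n pois(n; 1) R^n_{01} / P_01(1), computable in closed form
        model = MkModel(2, 1.0)
        p01 = model.transition_matrix(1.0)[0, 1]
        expected = 0.0
        pois = math.exp(-1.0)
        for n in range(0, 60):
            rn = (1 - (-1.0) ** n) / 2  # n-step prob of the jump chain, 0 -> 1
            expected += n * pois * rn / p01
            pois *= 1.0 / (n + 1)
        t = parse_newick("(A:1);")
        t.root.length = None
        counts = []
        maps = sample_stochastic_maps(
            t, {"A": 1}, MkModel(2, 1.0, root_prior=(1.0, 0.0)), n_maps=4000, seed=7
        )
        for m in maps.maps:
            segs = m.branch_segments[frozenset({"A"})]
            counts.append(len(segs) - 1)
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)


class TestSummarize:
    def test_identical_maps_give_indicator_posteriors(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        char = {"A": 1, "B": 1, "C": 1}
        maps = sample_stochastic_maps(t, char, MkModel(2, 0.0), n_maps=5, seed=0)
        summary = summarize_maps(maps)
        for clade, p in summary.posterior.probs.items():
            assert p == pytest.approx([0.0, 1.0])

    def test_single_map_summary_matches_that_map(self):
        rng = np.random.default_rng(5)
        tree = random_rooted_tree(rng, 5)
        char = {l.label: int(rng.integers(2)) for l in tree.leaves()}
        maps = sample_stochastic_maps(tree, char, MkModel(2, 1.0), n_maps=1, seed=2)
        summary = summarize_maps(maps)
        only = maps.maps[0]
        for clade, p in summary.posterior.probs.items():
            assert p[only.node_states[clade]] == 1.0

    def test_posterior_convergence_rate(self):
        tree, _ = sim_species_tree(6, 1.0, seed=8)
        tips, _, _ = sim_discrete_character(tree, 1.0, 2, seed=9)
        if len(set(tips.values())) < 2:
            tips[sorted(tips)[0]] = 1 - tips[sorted(tips)[0]]
        model = MkModel(2, 1.0)
        exact = marginal_posteriors(tree, tips, model)

        def linf(n_maps, seed):
            maps = sample_stochastic_maps(tree, tips, model, n_maps=n_maps, seed=seed)
            freq = summarize_maps(maps).posterior
            return max(
                float(np.abs(freq[c] - exact[c]).max()) for c in exact.probs
            )

        assert linf(10000, 1) < linf(100, 1) + 0.01
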