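import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcmnet import (
    GeneModule,
    ModuleSet,
    PRESETS,
    QCMParams,
    WeightedGeneNetwork,
    density_lower_bound,
    expansion_decay_factor,
    merge_modules,
    mine_modules,
    module_density,
    overlap_ratio,
    random_subset_density_baseline,
)
from conftest import random_weighted_network


class TestModuleDensity:
    def test_two_genes_density_is_edge_weight(self):
        net = WeightedGeneNetwork(weights={("a", "b"): 0.7}, n_datasets=1)
        assert module_density({"a", "b"}, net) == 0.7

    def test_complete_unit_graph_has_density_one(self, unit_triangle):
        assert module_density({"a", "b", "c"}, unit_triangle) == 1.0

    def test_missing_edges_count_as_zero(self):
        net = WeightedGeneNetwork(
            weights={("a", "b"): 1.0, ("a", "c"): 0.5}, n_datasets=1
        )
        assert module_density({"a", "b", "c"}, net) == pytest.approx(0.5)

    def test_rejects_singleton(self, unit_triangle):
        with pytest.raises(ValueError):
            module_density({"a"}, unit_triangle)


class TestExpansionDecay:
    def test_reference_values(self):
        assert expansion_decay_factor(2, QCMParams(lambda_=2.0, t=1.0)) == pytest.approx(
            1 - 1 / 12
        )
        assert expansion_decay_factor(2, QCMParams(lambda_=0.5, t=0.0)) == pytest.approx(0.5)

    def test_approaches_one_for_large_lambda(self):
        assert expansion_decay_factor(2, QCMParams(lambda_=1e9, t=1.0)) == pytest.approx(
            1.0, abs=1e-9
        )

    @given(st.integers(min_value=2, max_value=500))
    @settings(max_examples=40, derandomize=True)
    def test_strictly_increasing_in_module_size(self, k):
        p = QCMParams(lambda_=2.0, t=1.0)
        assert expansion_decay_factor(k + 1, p) > expansion_decay_factor(k, p)


class TestOverlapRatio:
    def test_shared_over_smaller(self):
        assert overlap_ratio({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(2 / 3)
        assert overlap_ratio({"a"}, {"b"}) == 0.0
        assert overlap_ratio({"a", "b"}, {"a", "b", "c", "d"}) == 1.0

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            overlap_ratio(set(), {"a"})


def brute_force_max_density_sets(network, size):
    """Enumerate all vertex subsets of a size; return those of maximal density."""
    genes = sorted(network.gene_ids)
    best, argbest = -1.0, []
    for subset in itertools.combinations(genes, size):
        d = module_density(subset, network)
        if d > best + 1e-12:
            best, argbest = d, [set(subset)]
        elif abs(d - best) <= 1e-12:
            argbest.append(set(subset))
    return best, argbest


def two_clique_network(clique_size, n_background, n_bg_edges, seed):
    genes_a = [f"a{i:02d}" for i in range(clique_size)]
    genes_b = [f"b{i:02d}" for i in range(clique_size)]
    bg = [f"z{i:02d}" for i in range(n_background)]
    weights = {}
    for grp in (genes_a, genes_b):
        for u, v in itertools.combinations(grp, 2):
            weights[(u, v)] = 1.0
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(bg, 2))
    for idx in rng.choice(len(pairs), size=min(n_bg_edges, len(pairs)), replace=False):
        weights[pairs[idx]] = 0.1
    return WeightedGeneNetwork(weights=weights, n_datasets=1), set(genes_a), set(genes_b)


class TestMineModules:
    def test_single_edge_network(self):
        net = WeightedGeneNetwork(weights={("a", "b"): 1.0}, n_datasets=1)
        result = mine_modules(net, QCMParams(min_module_size=2))
        assert len(result) == 1
        assert result.modules[0].genes == ("a", "b")
        assert result.modules[0].density == 1.0

    def test_seed_stop_rule_excludes_light_edges(self):
        # gamma * w_max = 0.5; the weight-0.4 edge must never seed a module
        net = WeightedGeneNetwork(
            weights={("a", "b"): 1.0, ("c", "d"): 0.4}, n_datasets=1
        )
        result = mine_modules(net, QCMParams(gamma=0.5))
        assert [m.seed_edge for m in result.modules] == [("a", "b")]

    def test_recovers_two_planted_cliques(self, default_params):
        net, clique_a, clique_b = two_clique_network(6, 20, 50, seed=1)
        result = mine_modules(net, default_params)
        mined = {m.gene_set for m in result.modules if m.size >= 3}
        assert frozenset(clique_a) in mined
        assert frozenset(clique_b) in mined

    def test_mined_cliques_are_brute_force_density_maxima(self, default_params):
        # small instance where exhaustive enumeration is feasible
        net, clique_a, clique_b = two_clique_network(4, 10, 8, seed=2)
        best, argbest = brute_force_max_density_sets(net, 4)
        assert best == 1.0
        assert sorted(map(tuple, map(sorted, argbest))) == sorted(
            [tuple(sorted(clique_a)), tuple(sorted(clique_b))]
        )
        mined = {m.gene_set for m in mine_modules(net, default_params).modules if m.size == 4}
        assert mined == {frozenset(clique_a), frozenset(clique_b)}

    def test_cancer_preset_parameters(self):
        p = PRESETS["cancer"]
        assert (p.gamma, p.beta, p.lambda_, p.t) == (0.8, 0.8, 2.0, 1.0)

    def test_stored_density_matches_recomputation(self, default_params):
        net = random_weighted_network(40, 0.3, seed=11)
        for m in mine_modules(net, default_params).modules:
            assert m.density == pytest.approx(module_density(m.genes, net), abs=1e-9)

    def test_density_lower_bound_holds(self, default_params):
        for seed in range(10):
            net = random_weighted_network(40, 0.3, seed=seed)
            result = mine_modules(net, default_params)
            for m in result.modules:
                assert m.density >= density_lower_bound(m, net, default_params) - 1e-9

    def test_invariant_to_edge_insertion_order(self, default_params):
        net = random_weighted_network(30, 0.4, seed=3)
        items = list(net.weights.items())
        rng = np.random.default_rng(0)
        rng.shuffle(items)
        shuffled = WeightedGeneNetwork(weights=dict(items), n_datasets=1)
        r1 = mine_modules(net, default_params)
        r2 = mine_modules(shuffled, default_params)
        assert [m.genes for m in r1.modules] == [m.genes for m in r2.modules]

    def test_empty_network_rejected(self, default_params):
        with pytest.raises(ValueError):
            mine_modules(WeightedGeneNetwork(weights={}, n_datasets=1), default_params)


class TestMergeModules:
    def _module_set(self, gene_sets, network):
        modules = [
            GeneModule(genes=tuple(s), density=module_density(s, network))
            for s in gene_sets
        ]
        return ModuleSet(modules=modules, params=QCMParams(), w_max=1.0)

    def _chain_network(self, genes):
        genes = sorted(genes)
        weights = {
            (genes[i], genes[j]): 0.5
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
        }
        return WeightedGeneNetwork(weights=weights, n_datasets=1)

    def test_merges_above_threshold(self):
        net = self._chain_network({"a", "b", "c", "d"})
        ms = self._module_set([{"a", "b", "c"}, {"b", "c", "d"}], net)
        merged = merge_modules(ms, net, threshold=0.3)
        assert len(merged) == 1
        assert merged.modules[0].genes == ("a", "b", "c", "d")

    def test_below_threshold_unchanged(self):
        net = self._chain_network({"a", "b", "c", "d", "e", "f", "g", "h", "i", "j"})
        sets = [{"a", "b", "c", "d", "e"}, {"e", "f", "g", "h", "i"}]  # overlap 0.2
        merged = merge_modules(self._module_set(sets, net), net, threshold=0.3)
        assert {m.gene_set for m in merged.modules} == {frozenset(s) for s in sets}

    def test_transitive_merge_reaches_fixed_point(self):
        # ratio(A,B)=0.8 merges first; then ratio(A|B, C)=0.4 pulls C in
        a = {"a1", "a2", "a3", "a4", "a5"}
        b = {"a1", "a2", "a3", "a4", "b1"}
        c = {"a1", "a2", "c1", "c2", "c3"}
        net = self._chain_network(a | b | c)
        merged = merge_modules(self._module_set([a, b, c], net), net, threshold=0.3)
        assert len(merged) == 1
        assert merged.modules[0].gene_set == frozenset(a | b | c)

    @pytest.mark.parametrize("threshold", [0.3, 0.8])
    def test_fixed_point_and_idempotence(self, threshold, default_params):
        net = random_weighted_network(40, 0.4, seed=7)
        mined = mine_modules(net, default_params)
        once = merge_modules(mined, net, threshold)
        for m1, m2 in itertools.combinations(once.modules, 2):
            assert overlap_ratio(m1.genes, m2.genes) < threshold
        twice = merge_modules(once, net, threshold)
        assert [m.genes for m in twice.modules] == [m.genes for m in once.modules]

    def test_output_ordered_by_size_descending(self, default_params):
        net = random_weighted_network(40, 0.4, seed=8)
        merged = merge_modules(mine_modules(net, default_params), net, 0.8)
        sizes = [m.size for m in merged.modules]
        assert sizes == sorted(sizes, reverse=True)


class TestRandomSubsetBaseline:
    def test_complete_unit_graph(self):
        genes = [f"g{i}" for i in range(8)]
        weights = {
            (genes[i], genes[j]): 1.0
            for i in range(8)
            for j in range(i + 1, 8)
        }
        net = WeightedGeneNetwork(weights=weights, n_datasets=1)
        out = random_subset_density_baseline(net, sizes=[3, 5], reps=50, seed=0)
        for mean, sd in out.values():
            assert mean == pytest.approx(1.0)
            assert sd == pytest.approx(0.0)

    def test_matches_closed_form_expectation(self):
        # each pair weighted 0.2 with probability 0.25 -> expected density 0.05
        rng = np.random.default_rng(12)
        genes = [f"g{i:02d}" for i in range(60)]
        weights = {
            (genes[i], genes[j]): 0.2
            for i in range(60)
            for j in range(i + 1, 60)
            if rng.random() < 0.25
        }
        net = WeightedGeneNetwork(weights=weights, n_datasets=1)
        out = random_subset_density_baseline(net, sizes=[10], reps=1000, seed=5)
        mean, sd = out[10]
        se = sd / math.sqrt(1000)
        assert abs(mean - 0.05) < 3 * se + 0.01

    def test_oversized_subset_rejected(self, unit_triangle):
        with pytest.raises(ValueError):
            random_subset_density_baseline(unit_triangle, sizes=[4], reps=5, seed=0)

    def test_seeded_reproducibility(self, unit_triangle):
        a = random_subset_density_baseline(unit_triangle, sizes=[2], reps=20, seed=9)
        b = random_subset_density_baseline(unit_triangle, sizes=[2], reps=20, seed=9)
        assert a == b
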