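import numpy as np
import pytest

from qcmnet import (
    QCMParams,
    WeightedGeneNetwork,
    build_frequency_network,
    dataset_high_correlation_pairs,
    generate_expression_collection,
)


@pytest.fixture
def unit_triangle():
    """Three genes pairwise connected with weight 1."""
    return WeightedGeneNetwork(
        weights={("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0},
        n_datasets=1,
    )


def random_weighted_network(n_nodes: int, edge_prob: float, seed: int) -> WeightedGeneNetwork:
    """Erdos-Renyi graph with uniform(0.05, 1) weights, deterministic per seed."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_nodes)]
    weights = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                weights[(genes[i], genes[j])] = float(rng.uniform(0.05, 1.0))
    if not weights:
        weights[(genes[0], genes[1])] = 0.5
    return WeightedGeneNetwork(weights=weights, n_datasets=1)


@pytest.fixture(scope="session")
def small_planted_run():
    """3 datasets x 200 genes with one planted rho=0.8 module, mined inputs ready."""
    datasets, truth = generate_expression_collection(
        n_genes=200,
        dataset_sizes=[50, 50, 50],
        modules=[{"size": 15, "rho": 0.8, "module_id": "M1"}],
        seed=42,
    )
    pair_sets = [dataset_high_correlation_pairs(d) for d in datasets]
    network = build_frequency_network(pair_sets)
    return datasets, truth, pair_sets, network


@pytest.fixture
def default_params():
    return QCMParams(gamma=0.5, lambda_=2.0, t=1.0, beta=0.8)
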