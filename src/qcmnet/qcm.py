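"""Weighted Quasi-Clique Merger (QCM): greedy dense-subgraph mining with merging.

The miner works on a weighted graph whose weights lie in [0, 1] (in this
package: the co-expression frequency network). Density of a vertex set is the
sum of induced edge weights over the number of possible pairs, so a complete
unit-weight graph has density 1 and absent edges count as 0.

Mining is iterative and greedy. The globally heaviest edge seeds the first
module and fixes w_max; each later module is seeded at the heaviest edge whose
endpoints are not both inside one earlier module, and mining stops once the
best available seed weight drops below gamma * w_max. A module grows by
repeatedly adding the outside vertex that yields the highest new density,
accepting the addition only while

    new_density >= current_density * (1 - 1 / (2 * lambda * (k + t)))

with k the current module size. The multiplicative decay factor increases
toward 1 with k, so density may erode slowly early on but is pinched late;
together (gamma, lambda, t) guarantee a lower bound on every mined module's
density: density >= seed_weight * prod_{k=2..N-1} decay(k).

Modules whose gene overlap ratio — shared genes over the size of the smaller
module — reaches beta are then merged iteratively; a second, looser merge pass
(default threshold 0.3) produces the final reported set.
"""

from __future__ import annotations

import hashlib
import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import GenePair, comb2
from .coexpression import WeightedGeneNetwork

logger = logging.getLogger(__name__)


@dataclass
class QCMParams:
    """Mining and merging parameters.

    gamma: minimum seed-edge weight as a fraction of the heaviest edge, (0, 1].
        High gamma yields fewer, tighter modules.
    lambda_, t: control the adaptive density-decay acceptance threshold during
        expansion (lambda_ >= 0.5, t >= 0).
    beta: overlap-ratio threshold for the mining-stage merge, (0, 1].
    final_merge_threshold: overlap-ratio threshold for the final merge pass.
    min_module_size: modules below this size are excluded from the final
        reported set only; they still participate in merging.
    """

    gamma: float = 0.5
    lambda_: float = 2.0
    t: float = 1.0
    beta: float = 0.8
    final_merge_threshold: float = 0.3
    min_module_size: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.lambda_ < 0.5:
            raise ValueError(f"lambda must be >= 0.5, got {self.lambda_}")
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if not 0.0 < self.final_merge_threshold <= 1.0:
            raise ValueError(
                f"final_merge_threshold must be in (0, 1], got {self.final_merge_threshold}"
            )
        if self.min_module_size < 2:
            raise ValueError(f"min_module_size must be >= 2, got {self.min_module_size}")


#: Parameter presets the mining was run with on real data collections.
PRESETS = {
    "cancer": QCMParams(gamma=0.8, beta=0.8, lambda_=2.0, t=1.0),
    "normal": QCMParams(gamma=0.7, beta=0.8, lambda_=2.0, t=1.0),
}


@dataclass
class GeneModule:
    """A mined quasi-clique: gene set, its density, and discovery provenance."""

    genes: tuple[str, ...]
    density: float
    seed_edge: GenePair | None = None
    trace: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("module needs at least 2 genes")
        self.genes = tuple(sorted(self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class ModuleSet:
    """Mined modules in discovery order, with the parameters and network fingerprint."""

    modules: list[GeneModule]
    params: QCMParams
    w_max: float
    source_hash: str = ""
    merged: bool = False

    def __len__(self) -> int:
        return len(self.modules)

    def filter_min_size(self, min_size: int | None = None) -> "ModuleSet":
        k = self.params.min_module_size if min_size is None else min_size
        return replace(self, modules=[m for m in self.modules if m.size >= k])


def network_fingerprint(network: WeightedGeneNetwork) -> str:
    """Order-independent sha256 fingerprint of a weighted network."""
    h = hashlib.sha256()
    for (u, v), w in sorted(network.weights.items()):
        h.update(f"{u}\t{v}\t{w:.12g}\n".encode())
    return h.hexdigest()[:16]


def module_density(genes, network: WeightedGeneNetwork) -> float:
    """Weighted density of a vertex set: sum of induced weights / (N choose 2)."""
    gene_list = sorted(set(genes))
    n = len(gene_list)
    if n < 2:
        raise ValueError(f"density needs >= 2 genes, got {n}")
    weights = network.weights
    total = 0.0
    for i in range(n):
        gi = gene_list[i]
        for j in range(i + 1, n):
            gj = gene_list[j]
            total += weights.get((gi, gj), 0.0)
    return total / comb2(n)


def expansion_decay_factor(k: int, params: QCMParams) -> float:
    """Multiplicative density-decay tolerance at module size k (strictly increasing)."""
    if k < 2:
        raise ValueError(f"module size must be >= 2, got {k}")
    return 1.0 - 1.0 / (2.0 * params.lambda_ * (k + params.t))


def overlap_ratio(a, b) -> float:
    """Shared genes over the size of the smaller set, in [0, 1]."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("overlap_ratio requires non-empty gene sets")
    return len(sa & sb) / min(len(sa), len(sb))


def _expand(seed: GenePair, seed_w: float, adj, params: QCMParams):
    """Greedy density expansion from a seed edge; returns (members, weight_sum, trace)."""
    u, v = seed
    members = {u, v}
    trace = [u, v] if u < v else [v, u]
    weight_sum = seed_w
    conn: dict[str, float] = defaultdict(float)
    for g in (u, v):
        for nb, w in adj[g].items():
            if nb not in members:
                conn[nb] += w
    while conn:
        k = len(members)
        # best candidate: max connection weight, ties to smallest gene id
        best = min(conn, key=lambda g: (-conn[g], g))
        gain = conn[best]
        new_sum = weight_sum + gain
        cur_density = weight_sum / comb2(k)
        new_density = new_sum / comb2(k + 1)
        if new_density < cur_density * expansion_decay_factor(k, params):
            break
        members.add(best)
        trace.append(best)
        weight_sum = new_sum
        del conn[best]
        for nb, w in adj[best].items():
            if nb not in members:
                conn[nb] += w
    return members, weight_sum, trace


def mine_modules(network: WeightedGeneNetwork, params: QCMParams | None = None) -> ModuleSet:
    """Mine quasi-clique modules from a weighted network (pre-merge).

    Deterministic: edges are ranked by (weight desc, pair lexicographic) and all
    expansion ties break to the lexicographically smallest gene, so the result
    is invariant to input ordering.
    """
    if params is None:
        params = QCMParams()
    if not network.weights:
        raise ValueError("cannot mine an empty network")
    adj = network.adjacency()
    edges = sorted(network.weights.items(), key=lambda kv: (-kv[1], kv[0]))
    w_max = edges[0][1]
    min_seed = params.gamma * w_max
    modules: list[GeneModule] = []
    gene_modules: dict[str, set[int]] = defaultdict(set)
    n_rejected_seeds = 0
    pos = 0  # edges before pos are consumed; containment only grows
    while pos < len(edges):
        (u, v), w = edges[pos]
        if gene_modules[u] & gene_modules[v]:
            pos += 1
            continue
        if w < min_seed:
            n_rejected_seeds = len(edges) - pos
            break
        members, _, trace = _expand((u, v), w, adj, params)
        density = module_density(members, network)
        idx = len(modules)
        modules.append(
            GeneModule(genes=tuple(members), density=density, seed_edge=(u, v) if u < v else (v, u), trace=trace)
        )
        for g in members:
            gene_modules[g].add(idx)
        pos += 1
    logger.info(
        "mined %d modules (w_max=%.4f, seed cutoff=%.4f, %d edges below cutoff at stop)",
        len(modules), w_max, min_seed, n_rejected_seeds,
    )
    return ModuleSet(
        modules=modules,
        params=params,
        w_max=w_max,
        source_hash=network_fingerprint(network),
    )


def merge_modules(
    module_set: ModuleSet,
    network: WeightedGeneNetwork,
    threshold: float,
) -> ModuleSet:
    """Iteratively merge the most-overlapping module pair until a fixed point.

    At each step the pair with the highest overlap ratio >= threshold (ties to
    the earliest pair) is replaced by its union, with density recomputed from
    the network. The result is ordered by size descending (then lexicographic)
    and no output pair has overlap ratio >= threshold, so a second application
    is a no-op.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    sets: list[set[str]] = [set(m.genes) for m in module_set.modules]
    while len(sets) > 1:
        best = None
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                r = len(sets[i] & sets[j]) / min(len(sets[i]), len(sets[j]))
                if r >= threshold and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is None:
            break
        _, i, j = best
        sets[i] = sets[i] | sets[j]
        del sets[j]
    ordered = sorted(sets, key=lambda s: (-len(s), tuple(sorted(s))))
    modules = [
        GeneModule(genes=tuple(s), density=module_density(s, network))
        for s in ordered
    ]
    return replace(module_set, modules=modules, merged=True)


def random_subset_density_baseline(
    network: WeightedGeneNetwork,
    sizes: list[int],
    reps: int = 1000,
    seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Null density scale: mean and sd of density over random gene subsets.

    For each requested size, draws ``reps`` uniform subsets of the network's
    node set and computes their weighted density. Mirrors the background check
    that mined module densities are compared against.
    """
    nodes = sorted(network.gene_ids)
    n = len(nodes)
    for size in sizes:
        if size < 2 or size > n:
            raise ValueError(f"subset size {size} out of range [2, {n}]")
    rng = np.random.default_rng(seed)
    index = {g: i for i, g in enumerate(nodes)}
    dense = np.zeros((n, n))
    for (u, v), w in network.weights.items():
        i, j = index[u], index[v]
        dense[i, j] = w
        dense[j, i] = w
    out: dict[int, tuple[float, float]] = {}
    for size in sizes:
        densities = np.empty(reps)
        for r in range(reps):
            idx = rng.choice(n, size=size, replace=False)
            densities[r] = dense[np.ix_(idx, idx)].sum() / 2.0 / comb2(size)
        out[size] = (float(densities.mean()), float(densities.std(ddof=1)))
    return out


def density_lower_bound(module: GeneModule, network: WeightedGeneNetwork, params: QCMParams) -> float:
    """The density guarantee for a freshly mined module: seed weight x decay product."""
    if module.seed_edge is None:
        raise ValueError("lower bound applies to pre-merge modules with a seed edge")
    seed_w = network.weights[module.seed_edge]
    bound = seed_w
    for k in range(2, module.size):
        bound *= expansion_decay_factor(k, params)
    return bound
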