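"""PPI enrichment of gene modules and generic gene-set over-representation.

A mined co-expression module is called PPI-enriched when its genes carry more
known protein-protein interactions among themselves than expected by chance.
Two complementary measures are provided:

* an exact upper-tail hypergeometric p-value, treating all unordered gene
  pairs over the declared universe as the population, the PPI edge list as the
  successes, and the module's internal pairs as the draws;
* an empirical z-score against a null built by repeatedly drawing random gene
  sets of the same size from the universe and counting their internal PPI hits
  (500 draws by default).

A generic gene-level over-representation test against GMT gene-set collections
(hypergeometric with Benjamini-Hochberg correction across sets) covers the
functional-annotation side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import GenePair, canonical_pair, comb2


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction pairs plus the eligible gene universe."""

    pairs: set[GenePair]
    universe: set[str]

    def __post_init__(self) -> None:
        self.pairs = {canonical_pair(a, b) for a, b in self.pairs}
        self.universe = set(self.universe) | {g for p in self.pairs for g in p}

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class EnrichmentResult:
    observed_hits: int
    null_mean: float
    null_sd: float
    z_score: float          # NaN when the null is degenerate
    p_hypergeom: float
    reps: int
    seed: int
    degenerate_null: bool = False
    null_counts: np.ndarray = field(default_factory=lambda: np.array([]))


def count_internal_ppi(genes, ppi: PPINetwork) -> int:
    """Number of PPI pairs with both endpoints inside the gene set."""
    gene_list = sorted(set(genes))
    pairs = ppi.pairs
    return sum(
        1
        for i, a in enumerate(gene_list)
        for b in gene_list[i + 1 :]
        if (a, b) in pairs
    )


def ppi_hypergeometric_pvalue(observed: int, module_size: int, ppi: PPINetwork) -> float:
    """Upper-tail hypergeometric P(X >= observed) for internal PPI pair count.

    Population: all unordered pairs over the PPI universe; successes: the PPI
    pairs; draws: the module's internal pairs.
    """
    if module_size < 2:
        raise ValueError(f"module_size must be >= 2, got {module_size}")
    n_universe = len(ppi.universe)
    if n_universe < module_size:
        raise ValueError(
            f"universe ({n_universe} genes) smaller than module ({module_size})"
        )
    population = comb2(n_universe)
    successes = ppi.n_pairs
    draws = comb2(module_size)
    if observed > draws or observed > successes:
        raise ValueError(
            f"observed={observed} exceeds draws={draws} or successes={successes}"
        )
    return float(stats.hypergeom.sf(observed - 1, population, successes, draws))


def ppi_zscore(
    genes,
    ppi: PPINetwork,
    reps: int = 500,
    seed: int = 0,
) -> EnrichmentResult:
    """Empirical PPI-enrichment z-score against same-size random gene sets.

    Draws ``reps`` uniform gene sets of the module's size from the universe,
    counts internal PPI hits in each to estimate the null mean and (sample)
    standard deviation, and reports z = (observed - mean) / sd. A degenerate
    null (sd = 0) is flagged and yields z = NaN rather than infinity.
    """
    gene_set = set(genes)
    if reps < 2:
        raise ValueError(f"need reps >= 2, got {reps}")
    universe = sorted(ppi.universe)
    k = len(gene_set)
    if k > len(universe):
        raise ValueError("module larger than PPI universe")
    observed = count_internal_ppi(gene_set, ppi)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(reps, dtype=int)
    if len(universe) <= 5000:
        # dense boolean adjacency makes each null count a submatrix sum
        index = {g: i for i, g in enumerate(universe)}
        adj = np.zeros((len(universe), len(universe)), dtype=bool)
        for a, b in ppi.pairs:
            i, j = index[a], index[b]
            adj[i, j] = adj[j, i] = True
        for r in range(reps):
            idx = rng.choice(len(universe), size=k, replace=False)
            null_counts[r] = int(adj[np.ix_(idx, idx)].sum()) // 2
    else:
        uni_arr = np.array(universe, dtype=object)
        for r in range(reps):
            draw = uni_arr[rng.choice(len(universe), size=k, replace=False)]
            null_counts[r] = count_internal_ppi(draw, ppi)
    mean = float(null_counts.mean())
    sd = float(null_counts.std(ddof=1))
    degenerate = sd == 0.0
    z = float("nan") if degenerate else (observed - mean) / sd
    return EnrichmentResult(
        observed_hits=observed,
        null_mean=mean,
        null_sd=sd,
        z_score=z,
        p_hypergeom=ppi_hypergeometric_pvalue(observed, k, ppi),
        reps=reps,
        seed=seed,
        degenerate_null=degenerate,
        null_counts=null_counts,
    )


def gene_set_overrepresentation(
    genes,
    collections: dict[str, set[str]],
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a module in each GMT gene set.

    Membership is gene-level: population = universe, successes = set & universe,
    draws = module & universe. Returns a DataFrame sorted by p-value with
    Benjamini-Hochberg q-values across all tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(genes) & universe
    rows = []
    for name, members in collections.items():
        members_in = set(members) & universe
        overlap = len(module & members_in)
        if members_in:
            p = float(
                stats.hypergeom.sf(
                    overlap - 1, len(universe), len(members_in), len(module)
                )
            )
        else:
            p = 1.0
        rows.append((name, len(members_in), overlap, p))
    table = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    else:
        table["q_value"] = []
    return table
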