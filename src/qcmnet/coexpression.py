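"""Per-dataset correlation analysis and the weighted co-expression frequency network.

The model: within each expression dataset (genes x samples), every gene pair is
scored by the absolute Pearson correlation coefficient (|PCC|) of its expression
profiles. Because the |PCC| distribution varies between studies, the retention
threshold is set adaptively per dataset to the empirical 95th percentile of all
off-diagonal |PCC| values ("top 5%"). A pair's *frequency* — the fraction of
datasets in which it survives this cut — becomes its edge weight in the weighted
gene co-expression frequency network (WGCFN), so weights live in (0, 1] and an
edge of weight 1 is a pair highly correlated in every dataset.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import GenePair, canonical_pair, comb2

logger = logging.getLogger(__name__)

DEFAULT_QUANTILE = 0.95
#: Minimum samples per dataset for correlation significance; datasets below this
#: are flagged but (for synthetic runs) not rejected outright.
DEFAULT_MIN_SAMPLES = 30


@dataclass
class ExpressionDataset:
    """One study's genes x samples expression matrix."""

    dataset_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"dataset {self.dataset_id!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"dataset {self.dataset_id!r}: duplicate gene ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dataset_id: str) -> "ExpressionDataset":
        return cls(
            dataset_id=dataset_id,
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class CorrelationPairSet:
    """High-|PCC| gene pairs retained from one dataset, with the applied cutoff."""

    dataset_id: str
    pairs: set[GenePair]
    threshold_value: float
    quantile: float
    n_total_pairs: int = 0


@dataclass
class WeightedGeneNetwork:
    """The WGCFN: symmetric weighted graph with frequency weights in (0, 1]."""

    weights: dict[GenePair, float]
    n_datasets: int
    gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            self.gene_ids = {g for pair in self.weights for g in pair}

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def adjacency(self) -> dict[str, dict[str, float]]:
        adj: dict[str, dict[str, float]] = {g: {} for g in self.gene_ids}
        for (u, v), w in self.weights.items():
            adj[u][v] = w
            adj[v][u] = w
        return adj


def count_gene_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs, n(n-1)/2, exact integer arithmetic."""
    if n_genes < 2:
        raise ValueError(f"need at least 2 genes, got {n_genes}")
    return comb2(int(n_genes))


def collapse_probes(
    probe_matrix: ExpressionDataset, probe_to_gene: dict[str, str]
) -> ExpressionDataset:
    """Collapse a probe-level matrix to one row per gene.

    Probes without a gene annotation are dropped; for genes measured by several
    probes the probe with the highest mean expression across samples is kept
    (ties broken by the lexicographically smallest probe id).
    """
    means = probe_matrix.values.mean(axis=1)
    best: dict[str, tuple[float, str, int]] = {}
    n_unannotated = 0
    for i, probe in enumerate(probe_matrix.gene_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            n_unannotated += 1
            continue
        key = (-means[i], probe)
        if gene not in best or key < (-best[gene][0], best[gene][1]):
            best[gene] = (means[i], probe, i)
    if n_unannotated:
        logger.info(
            "collapse_probes[%s]: dropped %d unannotated probes",
            probe_matrix.dataset_id, n_unannotated,
        )
    if not best:
        raise ValueError(
            f"dataset {probe_matrix.dataset_id!r}: no probes with gene annotation"
        )
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return ExpressionDataset(
        dataset_id=probe_matrix.dataset_id,
        gene_ids=genes,
        sample_ids=list(probe_matrix.sample_ids),
        values=probe_matrix.values[rows],
    )


def pearson_correlation_matrix(dataset: ExpressionDataset) -> np.ndarray:
    """All-pairs Pearson correlation of gene expression profiles.

    Returns a symmetric genes x genes matrix with unit diagonal. Zero-variance
    genes have no defined correlation: their rows/columns are NaN and are never
    counted as high-correlation downstream.
    """
    if dataset.n_samples < 3:
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: need >= 3 samples for correlation, "
            f"got {dataset.n_samples}"
        )
    values = dataset.values
    sd = values.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        logger.warning(
            "dataset %s: %d zero-variance genes; correlations set to missing",
            dataset.dataset_id, int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    idx = np.where(~constant)[0]
    corr[idx, idx] = 1.0
    return corr


def pcc_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation under the null of no association.

    Based on the t statistic r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom;
    |r| = 1 returns 0 by convention.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if abs(r) > 1:
        raise ValueError(f"correlation out of range: {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def select_high_correlation_pairs(
    corr: np.ndarray,
    gene_ids: list[str],
    dataset_id: str = "",
    quantile: float = DEFAULT_QUANTILE,
) -> CorrelationPairSet:
    """Retain the gene pairs in the top (1 - quantile) tail of |PCC|.

    The cutoff is the nearest-rank empirical quantile of all off-diagonal |PCC|
    values (the value of rank ceil(q*M) in ascending order among the M defined
    pairs); every pair with |PCC| >= cutoff is kept, so ties at the threshold
    are included and the retained fraction can slightly exceed 1 - quantile.
    Missing (NaN) correlations — e.g. zero-variance genes — are never retained.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n) or n != len(gene_ids):
        raise ValueError("correlation matrix shape does not match gene_ids")
    iu, ju = np.triu_indices(n, k=1)
    vals = np.abs(corr[iu, ju])
    defined = np.isfinite(vals)
    m = int(defined.sum())
    if m == 0:
        raise ValueError(f"dataset {dataset_id!r}: all correlations missing")
    finite_vals = vals[defined]
    rank = math.ceil(quantile * m)  # nearest-rank, 1-based
    threshold = float(np.partition(finite_vals, rank - 1)[rank - 1])
    keep = defined & (vals >= threshold)
    gene_arr = np.asarray(gene_ids, dtype=object)
    pairs = {
        canonical_pair(str(a), str(b))
        for a, b in zip(gene_arr[iu[keep]], gene_arr[ju[keep]])
    }
    logger.info(
        "dataset %s: retained %d/%d pairs at |PCC| >= %.4f (q=%.3f)",
        dataset_id, len(pairs), m, threshold, quantile,
    )
    return CorrelationPairSet(
        dataset_id=dataset_id,
        pairs=pairs,
        threshold_value=threshold,
        quantile=quantile,
        n_total_pairs=m,
    )


def dataset_high_correlation_pairs(
    dataset: ExpressionDataset,
    quantile: float = DEFAULT_QUANTILE,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> CorrelationPairSet:
    """Convenience: correlation matrix + adaptive top-tail selection for one dataset."""
    if dataset.n_samples < min_samples:
        logger.warning(
            "dataset %s has %d samples (< %d); correlation estimates are noisy",
            dataset.dataset_id, dataset.n_samples, min_samples,
        )
    corr = pearson_correlation_matrix(dataset)
    return select_high_correlation_pairs(
        corr, dataset.gene_ids, dataset_id=dataset.dataset_id, quantile=quantile
    )


def build_frequency_network(
    pair_sets: list[CorrelationPairSet],
) -> WeightedGeneNetwork:
    """Build the WGCFN: edge weight = fraction of datasets retaining the pair."""
    if not pair_sets:
        raise ValueError("need at least one pair set")
    counts: Counter[GenePair] = Counter()
    for ps in pair_sets:
        counts.update(ps.pairs)
    if not counts:
        raise ValueError("no retained pairs in any dataset")
    n = len(pair_sets)
    weights = {pair: c / n for pair, c in counts.items()}
    return WeightedGeneNetwork(weights=weights, n_datasets=n)
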