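"""Synthetic multi-dataset expression collections with planted co-expression modules.

The generator emulates the study design the pipeline targets: a collection of
independent expression datasets (one per study) that share a gene universe, in
which a handful of gene modules are tightly co-expressed, each module active in
a configurable subset of the datasets. Matched PPI networks (dense inside
modules, sparse outside) and two-group survival cohorts with a controlled
hazard ratio provide ground truth for the enrichment and stratification stages.

Planted correlation uses a latent single-factor Gaussian model: in a dataset
where module m (intra-module correlation rho) is active, every module gene's
expression in sample s is

    sqrt(rho) * f_s + sqrt(1 - rho) * eps_{g,s}

with f_s a per-(module, dataset) factor and eps i.i.d. standard normal. All
module gene pairs then have population correlation exactly rho, and the factor
is dataset-local, so correlation structure does not leak across datasets. All
other entries are i.i.d. standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import GenePair, canonical_pair
from .coexpression import ExpressionDataset
from .survival import SurvivalRecord

DEFAULT_RHO = 0.8


@dataclass
class PlantedModule:
    """Ground-truth module: genes, intra-module correlation, datasets where active."""

    module_id: str
    genes: frozenset[str]
    rho: float = DEFAULT_RHO
    presence: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        self.presence = frozenset(self.presence)
        if not self.genes:
            raise ValueError(f"module {self.module_id!r}: empty gene set")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"module {self.module_id!r}: rho must be in [0, 1], got {self.rho}")


@dataclass
class SyntheticTruth:
    """Everything needed to score a mining run against the planted structure."""

    modules: list[PlantedModule]
    universe: list[str]
    dataset_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        uni = set(self.universe)
        dsets = set(self.dataset_ids)
        for m in self.modules:
            if not m.genes <= uni:
                raise ValueError(f"module {m.module_id!r}: genes outside universe")
            if not m.presence <= dsets:
                raise ValueError(f"module {m.module_id!r}: presence outside dataset ids")

    def module_by_id(self, module_id: str) -> PlantedModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)


def gene_labels(n: int, prefix: str = "G") -> list[str]:
    """Zero-padded gene ids ('G00001', ...) so lexicographic tie-breaks are stable."""
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _resolve_modules(module_specs, universe, dataset_ids, allow_overlap):
    resolved: list[PlantedModule] = []
    cursor = 0
    for spec in module_specs:
        if isinstance(spec, PlantedModule):
            resolved.append(spec)
            continue
        spec = dict(spec)
        size = spec.pop("size", None)
        genes = spec.pop("genes", None)
        if genes is None:
            if size is None:
                raise ValueError("module spec needs 'genes' or 'size'")
            genes = universe[cursor : cursor + size]
            if len(genes) < size:
                raise ValueError("not enough genes in universe for requested module sizes")
            cursor += size
        presence = spec.pop("presence", dataset_ids)
        resolved.append(
            PlantedModule(
                module_id=spec.pop("module_id", f"M{len(resolved) + 1}"),
                genes=frozenset(genes),
                rho=spec.pop("rho", DEFAULT_RHO),
                presence=frozenset(presence),
            )
        )
        if spec:
            raise ValueError(f"unknown module spec keys: {sorted(spec)}")
    if not allow_overlap:
        seen: set[str] = set()
        for m in resolved:
            clash = seen & m.genes
            if clash:
                raise ValueError(
                    f"planted modules overlap (e.g. {sorted(clash)[:3]}); "
                    "pass allow_overlap=True to permit this"
                )
            seen |= m.genes
    return resolved


def generate_expression_collection(
    n_genes: int,
    dataset_sizes: list[int],
    modules,
    seed: int,
    allow_overlap: bool = False,
) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Generate one expression dataset per entry of ``dataset_sizes``.

    ``modules`` is a list of PlantedModule objects or dict specs with keys
    ``size`` (or explicit ``genes``), ``rho``, ``presence`` and ``module_id``;
    sized specs are assigned disjoint blocks of the universe in order.
    Deterministic for a given seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if not dataset_sizes:
        raise ValueError("need at least one dataset")
    for s in dataset_sizes:
        if s < 3:
            raise ValueError(f"every dataset needs >= 3 samples, got {s}")
    universe = gene_labels(n_genes)
    dataset_ids = [f"D{i:02d}" for i in range(1, len(dataset_sizes) + 1)]
    resolved = _resolve_modules(modules, universe, dataset_ids, allow_overlap)
    for m in resolved:
        if len(m.genes) > n_genes:
            raise ValueError(f"module {m.module_id!r} larger than universe")

    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(universe)}
    datasets: list[ExpressionDataset] = []
    for dataset_id, n_samples in zip(dataset_ids, dataset_sizes):
        values = rng.standard_normal((n_genes, n_samples))
        for m in resolved:
            if dataset_id not in m.presence:
                continue
            factor = rng.standard_normal(n_samples)
            rows = sorted(gene_index[g] for g in m.genes)
            values[rows] = (
                np.sqrt(m.rho) * factor + np.sqrt(1.0 - m.rho) * values[rows]
            )
        samples = [f"{dataset_id}_S{j:03d}" for j in range(1, n_samples + 1)]
        datasets.append(
            ExpressionDataset(
                dataset_id=dataset_id,
                gene_ids=list(universe),
                sample_ids=samples,
                values=values,
            )
        )
    truth = SyntheticTruth(
        modules=resolved, universe=universe, dataset_ids=dataset_ids, seed=seed
    )
    return datasets, truth


def generate_ppi(
    truth: SyntheticTruth,
    p_in: float,
    p_out: float,
    seed: int,
) -> set[GenePair]:
    """Random PPI network matched to the planted modules.

    Every within-module gene pair is an edge with probability ``p_in``, every
    other pair over the universe with probability ``p_out``. Undirected,
    deduplicated, no self-pairs.
    """
    if not 0.0 <= p_out <= p_in <= 1.0:
        raise ValueError(f"need 0 <= p_out <= p_in <= 1, got p_in={p_in}, p_out={p_out}")
    rng = np.random.default_rng(seed)
    module_pairs: set[GenePair] = set()
    for m in truth.modules:
        genes = sorted(m.genes)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                module_pairs.add((genes[i], genes[j]))
    edges: set[GenePair] = set()
    universe = truth.universe
    for i in range(len(universe)):
        for j in range(i + 1, len(universe)):
            pair = (universe[i], universe[j])
            p = p_in if pair in module_pairs else p_out
            if p > 0 and rng.random() < p:
                edges.add(pair)
    return edges


def generate_survival_cohort(
    n_patients: int,
    module: PlantedModule,
    hazard_ratio: float,
    censor_fraction: float,
    seed: int,
    baseline_rate: float = 1.0 / 1000.0,
    shift: float = 1.5,
) -> tuple[ExpressionDataset, list[SurvivalRecord], dict[str, int]]:
    """Two-group cohort with group-dependent hazard and module-driven expression.

    Patients split evenly into groups 0 and 1. The groups differ in the *shape*
    of their module-gene expression profile: half the module genes have mean
    +shift in group 0 and -shift in group 1, the other half the reverse, so the
    two groups are separable under correlation distance (a uniform level shift
    would be removed by per-patient standardization). Event times are
    exponential with rates ``baseline_rate`` (group 0) and
    ``baseline_rate * hazard_ratio`` (group 1); a ``censor_fraction`` of
    patients is censored at a uniform time before their event.
    """
    if n_patients < 4:
        raise ValueError(f"need >= 4 patients, got {n_patients}")
    if hazard_ratio <= 0:
        raise ValueError(f"hazard_ratio must be positive, got {hazard_ratio}")
    if not 0.0 <= censor_fraction <= 1.0:
        raise ValueError(f"censor_fraction must be in [0, 1], got {censor_fraction}")
    rng = np.random.default_rng(seed)
    genes = sorted(module.genes)
    n_half = len(genes) // 2
    signs = np.array([1.0] * n_half + [-1.0] * (len(genes) - n_half))
    patient_ids = [f"P{i:04d}" for i in range(1, n_patients + 1)]
    groups = {pid: (0 if i < (n_patients + 1) // 2 else 1) for i, pid in enumerate(patient_ids)}

    values = np.empty((len(genes), n_patients))
    for j, pid in enumerate(patient_ids):
        sign = 1.0 if groups[pid] == 0 else -1.0
        values[:, j] = sign * shift * signs + rng.standard_normal(len(genes))
    expr = ExpressionDataset(
        dataset_id="cohort", gene_ids=genes, sample_ids=patient_ids, values=values
    )

    rates = np.array(
        [baseline_rate * (hazard_ratio if groups[p] else 1.0) for p in patient_ids]
    )
    event_times = rng.exponential(1.0 / rates)
    n_censored = int(round(censor_fraction * n_patients))
    censored_idx = set(rng.choice(n_patients, size=n_censored, replace=False).tolist())
    records = []
    for i, pid in enumerate(patient_ids):
        if i in censored_idx:
            records.append(
                SurvivalRecord(
                    patient_id=pid,
                    time=float(rng.uniform(0.0, event_times[i])),
                    event=False,
                )
            )
        else:
            records.append(SurvivalRecord(patient_id=pid, time=float(event_times[i]), event=True))
    return expr, records, groups


def module_recovery_score(mined, truth: SyntheticTruth) -> dict[str, float]:
    """Best Jaccard index over mined modules, per planted module (0 if none mined).

    ``mined`` may be a ModuleSet or any iterable of gene collections.
    """
    mined_sets = [
        set(m.genes) if hasattr(m, "genes") else set(m)
        for m in (mined.modules if hasattr(mined, "modules") else mined)
    ]
    scores: dict[str, float] = {}
    for planted in truth.modules:
        best = 0.0
        for s in mined_sets:
            inter = len(planted.genes & s)
            union = len(planted.genes | s)
            if union:
                best = max(best, inter / union)
        scores[planted.module_id] = best
    return scores
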