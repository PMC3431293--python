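"""Plain-text readers and writers for all pipeline artifacts.

Everything is tab-separated text: expression matrices (genes x samples with a
header row), pair sets and networks as 3-column edge lists with the
lexicographically smaller gene first, module tables, GMT gene-set collections,
PPI edge lists, and TCGA-style clinical tables. Writers emit lexicographically
ordered, newline-terminated output so runs are diff-stable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import canonical_pair
from .coexpression import CorrelationPairSet, ExpressionDataset, WeightedGeneNetwork
from .enrichment import PPINetwork
from .qcm import ModuleSet

logger = logging.getLogger(__name__)


def read_expression_tsv(path) -> ExpressionDataset:
    """Read a genes x samples TSV (first column gene id, header row of sample ids).

    Ragged rows, non-numeric cells and duplicate gene ids raise errors naming
    the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ValueError(f"{path}: header has no sample columns")
    gene_ids: list[str] = []
    seen: dict[str, int] = {}
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        gene = fields[0]
        if gene in seen:
            raise ValueError(
                f"{path}: line {lineno}: duplicate gene id {gene!r} "
                f"(first seen on line {seen[gene]})"
            )
        seen[gene] = lineno
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
        gene_ids.append(gene)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return ExpressionDataset(
        dataset_id=path.stem,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
    )


def write_expression_tsv(dataset: ExpressionDataset, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(dataset.sample_ids) + "\n")
        for gene, row in zip(dataset.gene_ids, dataset.values):
            fh.write(gene + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def write_pair_set_tsv(pair_set: CorrelationPairSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dataset={pair_set.dataset_id}\tthreshold={pair_set.threshold_value!r}"
                 f"\tquantile={pair_set.quantile!r}\tn_total_pairs={pair_set.n_total_pairs}\n")
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(pair_set.pairs):
            fh.write(f"{a}\t{b}\n")


def read_pair_set_tsv(path) -> CorrelationPairSet:
    path = Path(path)
    dataset_id, threshold, quantile, n_total = path.stem, float("nan"), float("nan"), 0
    pairs = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("# ").split("\t"):
                    key, _, val = token.partition("=")
                    if key == "dataset":
                        dataset_id = val
                    elif key == "threshold":
                        threshold = float(val)
                    elif key == "quantile":
                        quantile = float(val)
                    elif key == "n_total_pairs":
                        n_total = int(val)
                continue
            if line.startswith("gene_a\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            pairs.add(canonical_pair(fields[0], fields[1]))
    return CorrelationPairSet(
        dataset_id=dataset_id, pairs=pairs, threshold_value=threshold,
        quantile=quantile, n_total_pairs=n_total,
    )


def write_network_tsv(network: WeightedGeneNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_datasets={network.n_datasets}\n")
        fh.write("gene_a\tgene_b\tweight\n")
        for (a, b), w in sorted(network.weights.items()):
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_network_tsv(path) -> WeightedGeneNetwork:
    path = Path(path)
    weights = {}
    n_datasets = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key == "n_datasets":
                    n_datasets = int(val)
                continue
            if line.startswith("gene_a\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            weights[canonical_pair(fields[0], fields[1])] = float(fields[2])
    if not weights:
        raise ValueError(f"{path}: no edges")
    return WeightedGeneNetwork(weights=weights, n_datasets=n_datasets)


def write_modules_tsv(module_set: ModuleSet, path) -> None:
    """One row per (module, gene): module_id, gene, module_size, density."""
    with open(path, "w") as fh:
        fh.write("module_id\tgene\tmodule_size\tdensity\n")
        for i, module in enumerate(module_set.modules, start=1):
            for gene in module.genes:
                fh.write(f"M{i:03d}\t{gene}\t{module.size}\t{module.density!r}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT collection: name <tab> description <tab> gene ... per line."""
    path = Path(path)
    collections: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs name, description and >= 1 gene"
                )
            name = fields[0]
            if name in collections:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            collections[name] = {g for g in fields[2:] if g}
    if not collections:
        raise ValueError(f"{path}: empty GMT file")
    return collections


def read_ppi_tsv(path, universe=None) -> PPINetwork:
    """Read a 2-column PPI edge list; duplicates and self-pairs dropped (logged)."""
    path = Path(path)
    pairs = set()
    n_self = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_a\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            pair = canonical_pair(a, b)
            if pair in pairs:
                n_dup += 1
            pairs.add(pair)
    if n_self or n_dup:
        logger.info("read_ppi_tsv: dropped %d self-pairs, %d duplicates", n_self, n_dup)
    return PPINetwork(pairs=pairs, universe=set(universe) if universe else set())


def write_ppi_tsv(pairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def read_clinical_tsv(path) -> pd.DataFrame:
    """Read a TCGA-style clinical table, validating the required columns."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "vital_status", "days_to_death", "days_to_last_followup"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns: {sorted(missing)}")
    return table


def write_clinical_tsv(records, groups, path) -> None:
    """Write survival records (optionally with true group labels) as clinical TSV."""
    with open(path, "w") as fh:
        cols = "patient_id\tvital_status\tdays_to_death\tdays_to_last_followup"
        if groups is not None:
            cols += "\tgroup"
        fh.write(cols + "\n")
        for r in sorted(records, key=lambda r: r.patient_id):
            if r.event:
                row = f"{r.patient_id}\tDECEASED\t{r.time!r}\t"
            else:
                row = f"{r.patient_id}\tLIVING\t\t{r.time!r}"
            if groups is not None:
                row += f"\t{groups[r.patient_id]}"
            fh.write(row + "\n")


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
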