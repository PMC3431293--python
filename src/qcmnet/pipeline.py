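"""End-to-end pipeline: correlate -> frequency network -> mine -> merge (-> report).

A PipelineConfig either points at existing expression TSV files or embeds a
simulation spec for the synthetic generator. One global seed fans out to
per-stage seeds through numpy SeedSequence spawning, so each stage is
independently reproducible; two runs with the same config and seed produce
byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as qio
from ._util import spawn_seeds
from .coexpression import (
    DEFAULT_MIN_SAMPLES,
    DEFAULT_QUANTILE,
    build_frequency_network,
    dataset_high_correlation_pairs,
)
from .qcm import QCMParams, merge_modules, mine_modules
from .synthetic import generate_expression_collection, module_recovery_score

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Configuration for a full mining run."""

    output_dir: str
    expression_paths: list[str] = field(default_factory=list)
    simulate: dict | None = None
    params: QCMParams = field(default_factory=QCMParams)
    quantile: float = DEFAULT_QUANTILE
    min_samples: int = DEFAULT_MIN_SAMPLES
    seed: int = 0
    write_intermediates: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = QCMParams(**raw.pop("params", {}))
        return cls(params=params, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return the run manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_seed, _spare = spawn_seeds(config.seed, 2)

    truth = None
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", sim_seed)
        datasets, truth = generate_expression_collection(**sim)
        logger.info("simulated %d datasets of %d genes", len(datasets), datasets[0].n_genes)
    elif config.expression_paths:
        for p in config.expression_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"expression file not found: {p}")
        datasets = [qio.read_expression_tsv(p) for p in config.expression_paths]
    else:
        raise ValueError("config needs expression_paths or a simulate block")

    pair_sets = []
    for ds in datasets:
        ps = dataset_high_correlation_pairs(
            ds, quantile=config.quantile, min_samples=config.min_samples
        )
        pair_sets.append(ps)
        if config.write_intermediates:
            qio.write_pair_set_tsv(ps, out / f"pairs_{ds.dataset_id}.tsv")

    network = build_frequency_network(pair_sets)
    if config.write_intermediates:
        qio.write_network_tsv(network, out / "wgcfn.tsv")

    mined = mine_modules(network, config.params)
    beta_merged = merge_modules(mined, network, config.params.beta)
    final = merge_modules(beta_merged, network, config.params.final_merge_threshold)
    reported = final.filter_min_size()

    qio.write_modules_tsv(mined, out / "modules_premerge.tsv")
    qio.write_modules_tsv(reported, out / "modules_final.tsv")

    manifest = {
        "tool_version": __version__,
        "seed": config.seed,
        "params": {
            "gamma": config.params.gamma,
            "lambda": config.params.lambda_,
            "t": config.params.t,
            "beta": config.params.beta,
            "final_merge_threshold": config.params.final_merge_threshold,
            "min_module_size": config.params.min_module_size,
            "quantile": config.quantile,
            "min_samples": config.min_samples,
        },
        "n_datasets": len(datasets),
        "pairs_retained": {ps.dataset_id: len(ps.pairs) for ps in pair_sets},
        "wgcfn_edges": network.n_edges,
        "wgcfn_genes": len(network.gene_ids),
        "w_max": mined.w_max,
        "modules_premerge": len(mined),
        "modules_post_beta_merge": len(beta_merged),
        "modules_post_final_merge": len(final),
        "modules_reported": len(reported),
    }
    if truth is not None:
        scores = module_recovery_score(reported, truth)
        manifest["planted_module_recovery_jaccard"] = scores
    qio.write_manifest(manifest, out / "manifest.json")
    return manifest
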