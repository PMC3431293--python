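# qcmnet

Frequent gene co-expression network mining with the weighted Quasi-Clique
Merger (QCM), plus downstream protein-interaction enrichment and survival
stratification.

## The problem

A single expression study yields co-expression clusters that often fail to
reproduce in the next study. `qcmnet` targets the modules that recur: given a
collection of expression datasets (genes × samples, one matrix per study), it
keeps each dataset's top 5% of gene pairs by |PCC| (the threshold is the
nearest-rank 95th percentile per dataset, so studies with different
correlation scales are treated fairly) and builds a **weighted gene
co-expression frequency network** (WGCFN) whose edge weights
w_ij ∈ (0, 1] are the fraction of datasets in which pair (i, j) survives the
cut. Dense subgraphs of this network are gene modules co-expressed across many
studies, not just one.

Modules are mined with the weighted QCM algorithm. The density of a module S
with N genes is

    d(S) = Σ_{i<j ∈ S} w_ij / (N(N−1)/2)  ∈ [0, 1].

Mining seeds at the heaviest edge not already inside a mined module (stopping
when the best seed falls below γ·w_max) and greedily adds the vertex that
maximizes density, accepting while d_new ≥ d_current·(1 − 1/(2λ(k+t))). The
triple (γ, λ, t) guarantees every mined module's density is at least the seed
weight times the cumulative decay product. Modules overlapping by ≥ β
(shared genes / smaller module) are merged iteratively, with a final 30%
overlap pass consolidating near-duplicates.

Downstream, a module can be scored for PPI enrichment (exact hypergeometric
over gene pairs, plus an empirical z-score against 500 same-size random gene
sets) and for prognostic value (patients clustered into two groups by K-means
under correlation distance on the module genes, 100 restarts, compared by
Kaplan-Meier curves and the log-rank test).

A synthetic-data generator plants block-correlated modules (latent
single-factor model with exact pairwise correlation ρ), matched PPI networks
and two-group survival cohorts with a controlled hazard ratio, so the entire
pipeline is testable without external data. Who this is for: anyone mining
consensus co-expression structure across many expression studies, or wanting
a compact, fully tested reference implementation of weighted QCM.

## Worked example

`examples/mine_planted_modules.py` simulates 6 datasets (50 samples each, 500
genes) with two planted ρ = 0.8 modules, runs the full chain and prints:

```
WGCFN: 500 genes, 31616 edges
10 modules mined, 2 reported after merging:
  25 genes, density 1.000
  15 genes, density 1.000
background density (random 10-gene subsets): 0.0493
recovery Jaccard per planted module: {'M1': 1.0, 'M2': 1.0}
```

The two reported modules match the planted gene sets exactly (Jaccard 1.0)
with density 1.0 — every module pair survived the top-5% cut in every dataset
— against a random-subset background density of ~0.05, i.e. the mined
structure is ~20× denser than chance. `examples/ppi_enrichment.py` and
`examples/survival_stratification.py` walk the two downstream analyses the
same way (a planted PPI-dense module scores z ≈ 153 against the random-set
null; a hazard-ratio-3 cohort is stratified at log-rank p ≈ 3.5e-8).

The same stages are available as shell subcommands:

```bash
qcmnet simulate --n-genes 500 --n-datasets 6 --module-size 25 --seed 1 --out sim/
qcmnet correlate sim/D01.tsv --out pairs_D01.tsv      # ... one per dataset
qcmnet network pairs_*.tsv --out wgcfn.tsv
qcmnet mine wgcfn.tsv --gamma 0.6 --out modules.tsv
qcmnet pipeline --config config.yaml                  # everything at once
```

plus `enrich` and `survival` for the downstream stages; all accept `--seed`
and produce byte-identical outputs on reruns.

## Layout

- `src/qcmnet/` — `synthetic` (generators), `coexpression` (PCC, thresholds,
  WGCFN), `qcm` (miner, merging, density baseline), `enrichment`, `survival`,
  `io`/`pipeline` (TSV formats, YAML config, orchestration), `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model, parameters, numerical choices, limitations.
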