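# Methods

## The model

`qcmnet` mines gene modules that are *frequently* co-expressed across a
collection of expression studies, then asks two downstream questions about
each module: do its genes physically interact more than chance (PPI
enrichment), and does its expression pattern stratify patients into groups
with different survival?

### From expression matrices to a frequency network

For each dataset (genes × samples) the absolute Pearson correlation |PCC| is
computed for every gene pair. Because the |PCC| scale differs between studies,
a fixed cutoff would be biased; instead each dataset keeps its top 5% of pairs,
with the threshold defined as the nearest-rank (ceiling) empirical 95th
percentile of all off-diagonal |PCC| values. Ties at the threshold are
included (the `>=` rule), so the retained fraction can marginally exceed 5%;
with distinct values it lies in [0.05, 0.05 + 1/M] for M pairs. Correlations
involving zero-variance genes are undefined and are treated as missing, never
retained. The sign of the correlation is discarded after thresholding, so
strongly anti-correlated pairs also contribute edges.

The weighted gene co-expression frequency network (WGCFN) has an edge for each
pair retained in at least one dataset, weighted by the fraction of datasets
retaining it. Dividing by the dataset count keeps weights in (0, 1], which the
density definition below requires.

Two preprocessing utilities support real array data: probe collapsing keeps,
for each gene, the probe with the highest mean expression; a configurable
minimum-sample gate (default 30 samples, chosen so that the retained
correlations are individually significant at p < 0.05) warns on small
datasets rather than aborting, since synthetic runs legitimately use fewer.

### Weighted Quasi-Clique Merger

Density of a vertex set S with N = |S| is

    d(S) = sum of induced edge weights / (N(N-1)/2),

with absent edges contributing 0, so a complete unit-weight graph has density
1 and the measure is normalized to [0, 1].

Mining is greedy and iterative. The globally heaviest edge (weight w_max)
seeds the first module; each subsequent module is seeded at the heaviest edge
whose two endpoints do not both lie inside one previously mined module, and
mining stops when the best remaining seed weight drops below γ·w_max. A module
grows by repeatedly adding the outside vertex that maximizes the new density,
accepting the addition while

    d_new >= d_current * (1 - 1/(2λ(k + t))),    k = current module size.

The decay factor rises toward 1 with k, so density can erode early but is
pinched as modules grow; by induction every mined module satisfies

    d >= w_seed * prod_{k=2..N-1} (1 - 1/(2λ(k+t))),

the density guarantee the parameter triple (γ, λ, t) provides. Growth is by
vertices (all incident edges at once), since density is a vertex-set
functional; candidates are restricted to vertices with at least one edge into
the module, because zero-gain vertices cannot pass the threshold. All ties —
seed ranking and candidate choice — break to the lexicographically smallest
gene id, which makes mining deterministic and invariant to input ordering.

Merging is overlap-driven: the overlap ratio of two modules is the shared gene
count over the size of the smaller one. Modules are merged iteratively
(highest-ratio pair first) at the mining threshold β, then again in a looser
final pass (default 0.3); both thresholds are configurable because they play
different roles — β shapes the mined set, the final pass consolidates near-
duplicate modules for reporting. Merging runs strictly after mining. After
merging at threshold θ no output pair has ratio ≥ θ, so the operation is
idempotent. The minimum reported module size (default 10) filters only the
final set; small intermediate modules still participate in merging.

Defaults follow the published working ranges: λ = 2.0, t = 1.0, β = 0.8, γ in
0.5–0.9 with presets `cancer` (γ = 0.8) and `normal` (γ = 0.7). γ interacts
with the number of datasets: with few datasets the frequency scale is coarse
(weights are multiples of 1/n), and γ must exceed the largest frequency ratio
that background pairs reach by chance. With 10 datasets γ = 0.5 suffices;
with 3 datasets weight-2/3 coincidences are common and γ = 0.8 (seeds only in
pairs retained everywhere) is the appropriate setting.

A random-subset density baseline (mean/sd of density over uniformly drawn gene
subsets, 1000 repetitions at sizes 10 and 400 by default) provides the
background scale mined densities are compared against; on a top-5% frequency
network this background sits near 0.05 by construction.

### PPI enrichment

Two measures, deliberately on different footings:

* **Hypergeometric p**: population = all unordered gene pairs over the
  declared universe, successes = the PPI edge list, draws = the module's
  internal pairs, upper tail P(X ≥ observed). This pair-level population is
  one natural reading; the module's pairs are not an independent sample of
  pairs, so the p-value is reported as a ranking statistic, and the exact
  enumeration oracle in the tests pins the arithmetic rather than the
  sampling model.
* **Empirical z-score**: 500 random gene sets of the module's size are drawn
  from the universe; the internal-hit null mean and sample (n−1) sd give
  z = (observed − mean)/sd. A degenerate null (sd = 0) is flagged and yields
  NaN, never ±inf. The draws are stored in the result so the z-score can be
  recomputed exactly and reruns with the same seed are identical.

The ±3 band on z is a normal-reference statement: it is meaningful when the
null hit count is approximately normal, i.e. when its mean (≈ module-pairs ×
background edge density) is large enough (≳ 20). Calibration checks therefore
use modules of ~60 genes on a 1000-gene, 2%-density background (null mean
≈ 35); at small null means the count is Poisson-skewed and the upper tail of z
exceeds its nominal level — a property of the statistic, not of the
implementation.

Gene-set over-representation against GMT collections uses a gene-level
hypergeometric (population = universe, successes = set ∩ universe, draws =
module ∩ universe) with Benjamini–Hochberg q-values across sets. BH is an
explicit addition for multi-set screening; single-set p-values are unchanged
(q = p at m = 1).

### Survival stratification

Clinical tables follow the TCGA convention: LIVING patients are censored at
`days_to_last_followup`, all others contribute an event at `days_to_death`;
rows whose required day field is missing are excluded and counted in the log.

Patients are clustered on their module-gene expression vectors by K-means
with correlation distance, realized as Euclidean K-means on per-patient
vectors standardized to zero mean and unit norm — squared Euclidean distance
is then monotone in 1 − correlation, which keeps the inner loop a stock
solver. K-means runs 100 times from seeded random initializations and the
solution with minimal within-cluster dispersion is kept; labels are
canonicalized (group of the lexicographically smallest patient id = 0) and
the poor-outcome group is named post hoc as the one with the smaller
restricted mean survival. Constant patient vectors have no direction under
correlation distance and are rejected by name.

The Kaplan–Meier estimator and the two-group log-rank test (hypergeometric
at-risk model, χ² = (ΣO − ΣE)²/ΣV with 1 df) are implemented directly and
cross-checked in the test suite against lifelines to 1e-8 on random censored
cohorts. Zero-event inputs make the test undefined and raise. An optional
Bonferroni flag multiplies p by a declared comparison count, capped at 1.

## Synthetic data

The generator emulates the multi-dataset study design. Planted modules use a
latent single-factor Gaussian model: where module m (correlation ρ) is active,
gene g in sample s reads sqrt(ρ)·f_s + sqrt(1−ρ)·ε_{g,s}, giving exactly
exchangeable pairwise correlation ρ; the factor is drawn per (module,
dataset), so co-expression never leaks across datasets. Everything else is
i.i.d. standard normal. Default ρ = 0.8 — an engineering choice for "tightly
co-expressed", not an empirical estimate. Modules are disjoint unless
explicitly allowed to overlap. Gene ids are zero-padded ("G00001"), making
every lexicographic tie-break reproducible.

PPI networks are Bernoulli: p_in within modules, p_out elsewhere. Survival
cohorts split patients evenly into two groups with exponential event times at
rates r and r·HR (baseline r = 1/1000 days⁻¹) and uniform censoring before
the event for a chosen fraction. Group structure is encoded as anti-correlated
module-gene profile *shapes* (half the genes up in one group, down in the
other; default shift 1.5 sd), because the correlation-distance clustering
removes per-patient level and scale — a uniform shift would be invisible.

What the generator does not emulate: probe-level noise, batch effects,
platform normalization, heavy-tailed expression, correlated background genes,
non-exponential hazards, informative censoring. Passing tests therefore show
the pipeline recovers block-correlated structure under clean Gaussian
conditions with the claimed guarantees and calibrations; they do not certify
performance on real microarray collections.

## Problem sizes and numerical choices

The standard synthetic benchmark is 10 datasets × 50 samples over 1,000 genes
with planted modules of 30/20/15 genes (ρ = 0.8) plus a 15-gene module present
in a single dataset; mined at γ = 0.5, λ = 2, t = 1, β = 0.8, final merge 0.3.
The three recurrent modules are recovered with Jaccard ≥ 0.8 and the rare
module (maximum attainable weight 0.1 < γ·w_max) never seeds. Null
calibrations use 200 seeds for log-rank uniformity at HR = 1 (n = 100,
10% censoring) and 50 seeds for power at HR = 3 (n = 200); these sizes give
stable rates while keeping the whole benchmark in minutes on one core.

Numerical details: module densities are recomputed from the network after
expansion (no accumulated float drift; the stored value matches recomputation
to 1e-9); the expansion acceptance uses exact `>=` with no epsilon; quantile
thresholds use `np.partition` (exact nearest-rank, no interpolation);
p-values come from scipy's t, χ² and hypergeometric distributions; |PCC| = 1
maps to p = 0 by convention. One global seed fans out to per-stage seeds via
`numpy.random.SeedSequence.spawn`, so stages are independently reproducible
and identical configurations produce byte-identical output files.

## Known limitations

* The expansion acceptance rule is one defensible form of the adaptive
  density-decay threshold; it is isolated in `expansion_decay_factor` so
  alternatives can be swapped in.
* The pair-level hypergeometric population choice (pairs over the universe) is
  one of two plausible conventions; the code exposes the pieces to compute the
  other.
* Merging recomputes density on unions but does not re-expand merged modules;
  a merged module can have density below the pre-merge guarantee.
* β-merging runs after mining completes, not interleaved with it.
* K-means restarts with an empty cluster are handled by scikit-learn's
  re-initialization; the best-of-100 selection is by inertia only.
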