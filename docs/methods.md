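# Methods

## The variability route

At each timepoint the expression of a gene across the panel of genetically
identical individuals is treated as a sample from that timepoint's
between-individual distribution. For genes *i*, *j* and timepoint *t* with
individuals *1..n*:

- ρ_ij(t) = Spearman rank correlation of x_i(t,·) and x_j(t,·), average
  ranks on ties.
- Two-sided p: for n ≤ `exact_n_max` (default 9), the exact permutation
  null — the fraction of all n! orderings of one rank vector with
  |ρ| ≥ |ρ_obs|; the null distribution is cached per tie structure.
  Above that, the usual approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df.
  At the design's n = 14 the exact null (14! orderings) is out of reach,
  so the approximation is the operative path; this is a small, documented
  source of deviation from any exact-p analysis.
- Constant vectors leave ρ undefined: the pair is unscored at that
  timepoint (flagged, not an exception).

Selection is Benjamini–Hochberg step-up at FDR 10%, applied independently
within each timepoint over all pairs with a defined correlation there (m is
logged per timepoint, since both corrections depend on it). Pooling across
timepoints is available but off by default: each timepoint is computed and
thresholded as its own family.

**Persistence.** An edge survives iff some window of timepoint slots
(i) begins and ends on a significant slot, (ii) contains ≥ k significant
slots, and (iii) contains ≤ `gaps` non-significant slots. Defaults k = 4,
gaps = 1: significance at ZT 8, 10, 14 and 16 on the 2-hour grid passes
(one gap at ZT12). Requiring significant window ends prevents padding with
leading/trailing gaps. The ZT22→ZT0 wrap is off by default (the grid is
treated linearly) but available via `circular=True`. Loosening k can only
add edges — the k = 3 network is a superset of the k = 4 network, which is
the robustness comparison `compare_partitions` supports.

**Sign handling.** Both correlation signs are kept and recorded
per-timepoint; no sign-consistency across supporting timepoints is
required. A `positive_only` flag restricts to positive ρ.

**Missing data.** Values are absent (NaN), never zero. A pair is scored at
a timepoint on the individuals where both genes are observed, and only if
that joint count is ≥ `min_joint_obs` (default 8) — with a complete
14-individual design this is inert, but partial matrices degrade gracefully.

## The averaged time course route

Each gene is reduced to its mean-over-individuals profile across the 12
timepoints; Spearman is computed on profile pairs and an edge requires
p ≤ α/m (Bonferroni) with m the number of tested (non-constant) pairs.
α defaults to 0.05 and is exposed rather than tuned: the family-wise level
used in the emulated study is not published, only that it was conservative.

## Community detection

Louvain modularity maximization via `networkx.algorithms.community`
(seeded, resolution 1.0 by default), on unweighted edges — the network is
already thresholded, so edge presence rather than correlation strength
carries the signal; a |mean ρ|-weighted variant is available. Because
Louvain is stochastic, `restarts` (default 10 in the pipeline) reruns with
consecutive seeds and keeps the max-modularity partition; module ids are
relabeled contiguously from 0 by decreasing size (ties: smallest member
id), so runs are comparable. Singleton genes never enter the network and
therefore never enter partitions.

## Module analytics

- **Edge-time distribution**: an edge "detected at" a timepoint is one
  whose support mask is true there; a single edge contributes one count per
  supporting timepoint. Intra-module counts are audited against the
  network-wide totals on every pipeline run.
- **Night-edge percentage**: day is ZT ∈ [day_start, day_end), default
  [0, 12) for a 12L:12D cycle; undefined (flagged None) for modules with no
  detections. The detection-count convention (not per-edge majority vote)
  is the default because edge counts per timepoint are the primary
  readout; the alternative exists behind a flag at the summary level.
- **Enrichment**: Fisher's exact test on the 2×2 (in-module × in-set) table
  over a background that defaults to the network's genes (a
  whole-transcriptome background can be passed instead). Both one-sided and
  the two-sided p are reported — modules can be strongly enriched *or*
  depleted in HVGs. Odds ratios are Haldane-corrected (+0.5 per cell) when
  a cell is zero; the raw table is kept. A label-permutation p
  (`permutation_enrichment_p`) is available as a resampling alternative;
  it is not expected to match any specific published table.
- **Assortativity**: Pearson correlation of a node attribute over the
  endpoint lists of the module graph's edges, orientation-symmetrized
  (each edge contributes both (u,v) and (v,u)) — the standard attribute-
  assortativity convention — with a two-sided t p-value.
- **Z-scored profiles**: per gene, the mean-over-individuals profile
  centred and scaled by its **sample** standard deviation (ddof = 1);
  constant profiles are flagged and omitted.

## Synthetic data

One latent factor per module per timepoint:

    x[g,t,i] = μ_g(t) + λ_m(t)·F[m,t,i] + ε[g,t,i],   F ~ N(0,1)

with λ = σ√(ρ/(1−ρ)) so the expected within-module pairwise correlation
equals the spec's coupling ρ(t). The single-factor construction is
positive semidefinite by design and lets coupling switch on only inside a
window of timepoints — co-regulation at some moments of the cycle and not
others. HVG status multiplies both λ and the noise sd (default ×3), so HVG
modules stay internally correlated while being more dispersed. Mean
profiles come from a small library: 24-h sinusoid with a peak-ZT
parameter, square day/night wave, and flat.

The reference design (`default_spec`): 12 timepoints × 14 individuals;
three 20-gene modules at coupling 0.9 over six consecutive timepoints each
(day, night, and transition windows; sine/sine/flat mean profiles); 400
background genes with flat baselines U(6, 10) and unit noise; one HVG
module plus 20 HVG background genes, making the HVG tier 8.7% of genes.
The coupling magnitude is a calibration choice — the real inter-individual
correlation strength is not characterized — and the gene count is
deliberately desk-scale rather than transcriptome-scale (~20k). What
passing tests show is that the statistical machinery recovers this planted
structure; they do not certify behaviour under normalization artifacts,
count noise, or correlated backgrounds absent from the generator.

`evaluate_recovery` scores precision/recall against the union of
per-timepoint true edges and ARI between Louvain modules and planted
labels, restricted to genes planted in nonzero modules; planted genes
missing from the inferred partition count as singleton clusters (absence is
penalized rather than ignored).

## Numerical and scaling choices

- Per-timepoint correlation uses a full G×G rank-correlation matrix
  (`rankdata` + `corrcoef`); only BH-selected pairs are materialized, and
  full per-timepoint ρ vectors are recomputed just for surviving edges.
  Exact and fast to a few thousand genes; transcriptome-scale inputs would
  need a blocked pair iteration that this package does not implement.
- p-values are clamped into (0, 1] (perfect correlations map to the
  smallest positive float) so BH input contracts hold.
- Edge files are written in canonical (lexicographic) pair order, sorted,
  so identical inputs give byte-identical outputs; every run directory
  carries a SHA-256 manifest that `report` re-verifies before printing.
- One global seed fans out to per-stage seeds via SHA-256, so stages can
  be rerun in isolation with unchanged randomness.

## Limitations

- Edges are undirected co-expression; no directionality, partial
  correlation, or soft-threshold weighting.
- Gene identifiers are matched as exact strings; no ID mapping.
- Enrichment is generic Fisher/permutation set enrichment; no
  ontology-DAG-aware model.
- Exact module counts from Louvain are run-dependent by nature; only
  seeded runs are reproducible, and robustness should be judged via
  `compare_partitions` rather than by comparing raw module counts.
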