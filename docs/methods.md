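# Methods

This note documents the models, defaults and design choices behind
`somcoex`, and what its synthetic-data tests do and do not demonstrate
about real data.

## Study design and data model

The package targets a two-substrate (aspen `AH`, spruce `WH`), five
growth-point (GP1–GP5), duplicate bulk RNA-seq design: 10 conditions, 20
libraries. The unit of analysis is a gene-level integer count matrix;
everything upstream (alignment, counting) is out of scope. A *condition*
is a (substrate, growth point) pair; GP1 is the reference for all fold
differences. Gene and sample order is preserved end to end because
tie-breaking (best-matching-unit selection, modal-node identification) is
defined by order.

## Synthetic data generator

Counts are negative binomial with the mean–dispersion parameterization
`var = μ + α·μ²`, drawn as Gamma–Poisson. The mean of gene *g* in sample
*s* of condition *c* is

    μ_gs = scale_s · 2^( x_gc + ε_gs ),   ε_gs ~ N(0, σ_rep)

where `x_gc` is the gene's true log2 expression in that condition and
`scale_s` is the sample's library size (drawn uniformly from
`library_size_range`, then fixed) divided by the geometric mean of all
library sizes, so size factors are exercised and interpretable.

Planted structure:

- **Modules** (default 4 × 50 genes among 5,000): each module shares a
  single true profile built from a base level (uniform over
  `baseline_log2_mean_range`, default 3–9 log2 counts) and an effect
  amplitude (default 3 log2 units). Shapes cycle through *rising*
  (monotone increase by the full effect from GP1 to GP5, both substrates),
  *falling* (mirror), *substrate-divergent* (rises on the first substrate,
  falls from an elevated start on the second — a reversed profile across
  substrates), *late-burst* (flat until GP5), then *flat*.
- **Housekeeping controls** (default 27, split between chitin-synthase and
  NADH-dehydrogenase labels in the mock annotation table): exactly flat
  across all 10 conditions, with baselines drawn from the upper half of
  the baseline range — housekeeping controls are by construction
  well-expressed genes, and a lowly-expressed flat gene would be dominated
  by shot noise rather than biology.
- **Background**: flat per-gene baselines plus per-condition offsets
  `N(0, background_condition_sigma)` (default 0.3 log2). This models the
  modest condition-to-condition variation of unregulated genes in real
  time courses. It matters for QC: with a perfectly flat background,
  samples from different conditions correlate as tightly as replicates and
  replicate clustering carries no information. The offsets are part of the
  ground truth, and simulations that need an exact null (the DE
  calibration runs) set this to 0.

Default dispersion is α = 0.02, reflecting tightly controlled duplicate
cultures whose replicate libraries cluster pairwise before any
cross-condition merge; replicate noise is log-normal with σ_rep = 0.1
log2 units. These defaults give replicate Spearman ρ > 0.95. All draws
come from seeded `numpy` Generator streams (one per operation, derived
from the config seed); a fixed config is bit-reproducible.

The generator does **not** emulate: gene length or GC effects, batch
effects, correlated (non-module) gene–gene structure beyond shared
profiles, outlier samples, or count heaping. Tests passing on this data
therefore demonstrate algorithmic correctness and calibration under the
stated noise model, not robustness to those artefacts.

## Normalization and filtering

Two deliberately separate scalings:

- **CPM** (`count / library size × 10⁶`) for abundance reporting and the
  high-expression rule. Columns sum to 10⁶ exactly.
- **Median-of-ratios size factors** for everything model-facing: for each
  sample, the median over genes expressed in all samples of
  `count / geometric-mean(gene)`, rescaled to geometric mean 1 (the
  rescale makes factors pure relative-depth multipliers and is covered by
  a scale-equivariance test). Log2 values are `log2(count/factor + 1)`;
  the pseudocount of 1 keeps zero counts at exactly 0.

The gene filter keeps genes whose mean raw count across the replicates of
a condition strictly exceeds 5 reads. The phrase "per condition" is
ambiguous between *every* and *any* condition; the stricter all-conditions
reading is the default and the scope is a parameter (`scope="all"|"any"`).

Replicate QC computes Spearman ρ between all sample columns (Pearson on
average ranks; ties averaged; constant columns reported as missing) and
average-linkage clustering on `1 − ρ`. The per-condition
"replicates join first" indicator is reported, never enforced. The
housekeeping check flags annotated control genes whose per-condition mean
log2 values span more than 1.0 log2 units (configurable) — a growth- or
normalization-consistency alarm.

## Differential expression

Within each substrate, every growth point k > 1 is contrasted against
GP1. Fold differences are differences of mean log2-normalized values
(pseudocount-protected, hence always finite). Significance comes from a
simplified per-gene negative-binomial Wald test:

- normalized counts `y = k/s` have `Var(y) = μ/s + αμ²`;
- dispersion α is estimated per gene by the method of moments from
  *within-group* variability, pooled across the two groups by degrees of
  freedom;
- with duplicate libraries the per-gene estimate has one degree of
  freedom per group and is extremely noisy; using it directly makes the
  test anti-conservative exactly when the estimate undershoots. Every
  per-gene dispersion is therefore floored at the global median of the
  positive per-gene estimates (which doubles as the fallback for
  non-positive estimates) and at an absolute floor of 1e-8. Under an exact
  null (α = 0.1, 2+2 libraries) this yields a rejection rate of ~0.045 at
  p < 0.05, and with planted 3-log2-fold effects sensitivity ≈ 0.98 at
  an observed FDR ≈ 0.07 after Benjamini–Hochberg at 0.05;
- the Wald statistic is `z = (log(μ̂_A+½) − log(μ̂_B+½)) / SE` with the
  delta-method SE, two-sided normal p-value; a gene with zero counts in
  both groups gets p = 1.

There is no empirical-Bayes dispersion shrinkage, no fold-change
shrinkage, no outlier handling and no independent filtering: the intent
is the *contract* (NB test + BH at FDR < 0.05), not bit-compatibility with
any particular DE package. BH adjustment is the step-up rule
`adj_(i) = min_{j≥i} p_(j)·m/j`, capped at 1, verified against an
independent implementation. Adjustment is performed within each contrast.

## Self-organizing map

An online Kohonen SOM on a rectangular rows × cols lattice (default
24 × 20 = 480 nodes, 4-neighbour topology; node IDs 1..480 row-major).
Defaults follow the conventions of classic co-expression SOM pipelines:

- **Initialization**: codebooks sampled from data rows without
  replacement (seeded).
- **Budget**: 1000 presentations per node, i.e. 480,000 steps for the
  default grid. One "step" presents a single gene vector; with ~5,000
  genes that is ~100 passes. A `steps_mode="passes"` switch interprets the
  budget as full passes instead (presentations are the default because the
  map-size × 1000 rule counts updates, not sweeps).
- **Initial radius**: the 0.67 quantile (linear interpolation) of all
  pairwise Euclidean distances between lattice coordinates — the
  neighbour-distance convention. The quantile is configurable.
- **Schedules**: learning rate linear 0.05 → 0.01; radius linear from the
  initial radius to 1. The bubble neighbourhood is *strict* (`d < r`), so
  the final phase performs BMU-only updates.
- **No feature scaling** of input vectors: the map is trained directly on
  log2-normalized values and therefore separates genes by expression
  level as well as profile shape, which is what makes absolute-level node
  calls (the 95th-percentile criterion) meaningful.
- Ties in BMU search break to the lowest node ID; training is exactly
  reproducible given a seed.

Quantization error (mean gene-to-BMU distance) decreases through
training, but not dramatically: data-row initialization already places
codebooks inside the data cloud, so the initial QE is within ~15% of the
k-means floor for 480 centroids on the default data. The meaningful gains
from training are topological — planted-module genes end up on single or
adjacent nodes (in the default runs, ≥ 80% and typically 100% of each
module's genes land within lattice distance 2 of the module's modal
node, and module genes are closer on the lattice than random gene sets at
permutation p < 0.01).

## Node analysis

Node profiles average all member-gene × replicate log2 values per
condition; folds are node means of GPk minus GP1 within substrate. Empty
nodes have undefined profiles and are never called.

Condition-specific calls use two criteria, both strict:

1. node mean log2 expression > threshold, where the threshold is the 95th
   percentile (linear interpolation) of all gene × sample values, or a
   fixed override (e.g. 10.2 log2 units for a dataset where that is the
   95th percentile);
2. node log2 fold vs GP1 > 2.

They combine with `any` by default — either criterion suffices — with
`all` available; the procedural description of the original protocol uses
"either", while its figure caption reads as "and", and the procedural
source wins. Reference-GP conditions have no fold and can only satisfy
criterion 1 (under `all` they are never called). For a planted
substrate-divergent module the calls are directional: its modal node is
called at GP5 on the substrate where it rises and not on the substrate
where it falls (where its GP5 fold is negative). Simultaneous GP5 calls
on *both* substrates are impossible for a single divergent module by
construction; the directional asymmetry is the recovery criterion.

The high-expression rule operates on CPM: a gene passes at a (substrate,
growth point) if its replicate-mean CPM strictly exceeds 2.5 × the median
replicate-mean CPM of the scoped gene set at that condition. The scope
(all genes vs an annotation namespace such as CAZy) is configurable
because the median population of the published rule is ambiguous; the
default is all genes in the matrix. Medians are linear-interpolation
quantiles so boundary tests are exact.

Annotation overlays count member genes per node by (namespace, label),
with unannotated genes tallied explicitly; co-occurrence queries
(e.g. nodes holding both a P450 and a glutathione-S-transferase) are set
intersections over those counts. Tatami rendering draws one
rows × cols heat panel per condition with called nodes outlined.

## Problem sizes

Default test and acceptance runs use 5,000 genes (4 × 50 module genes, 27
housekeeping), the full 24 × 20 grid with its 480,000-step budget, a
2,000-gene exact-null calibration and a 5,500-gene power simulation —
sizes at which a full end-to-end run completes in well under a minute on
a single CPU while keeping every statistical check adequately powered.

## Known limitations

- The Wald test's global dispersion floor trades per-gene adaptivity for
  calibration at n = 2; genes with genuinely low dispersion lose a little
  power.
- With two replicates the dispersion cannot be checked per gene; the
  variance/mean relation is validated only in aggregate.
- The SOM is a local optimizer: node *identity* is seed-dependent, and
  only topological statements (co-location, lattice proximity) are
  stable across seeds.
- The high-expression and node-call thresholds are data-dependent
  quantiles; comparing absolute thresholds across datasets requires the
  fixed-override path.
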