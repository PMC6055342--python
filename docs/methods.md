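# Methods

This note documents the models, defaults and numerical choices behind
`tatamisom`, and what the synthetic benchmark does and does not establish.

## Normalization

Size factors use the median-of-ratios estimator: the pseudo-reference for
gene *g* is its geometric mean across libraries, the factor of library *j*
is the median over reference genes of `K_gj / geomean_g`, and the reference
set is the genes with a strictly positive count in every library. The
median is taken over the ratios themselves, not their logarithms — with an
even-sized reference set the two differ (arithmetic vs geometric mean of
the two middle ratios), and only the former matches the standard estimator.

Factors are **not** rescaled to geometric mean 1; users comparing against
implementations that do rescale should divide by `geomean(s)`. A
consequence worth knowing: multiplying one library's counts by *c* scales
its factor *relative to the others* by exactly *c*, but every individual
factor also absorbs a common `c^(1/n)` through the recomputed geometric
means, so absolute normalized values are only defined up to that shared
constant.

Expression is `log2(K/s + pseudocount)` with pseudocount 1 by default
(configurable; required positive whenever zeros are present). The high/low
threshold of 12 log2 therefore corresponds to ~4,100 size-factor-scaled
counts.

`MedianRatioNormalizer` follows the scikit-learn transformer contract
(libraries as rows); `fit` learns the per-gene reference, so new libraries
can be normalized against a frozen reference. The genes × samples helper
functions transpose internally.

## The self-organizing map

* **Grid.** 19 × 23 = 437 units by default — the near-square factorization
  of the 437-unit map size — on a rectangular lattice, node IDs 1..437
  row-major, so consecutive IDs within a row are laterally adjacent.
* **Features.** One observation per gene: its normalized log2 values across
  *all* replicate libraries (12 columns at default scale), not condition
  means. Replicate-level features let replicate noise inform the map.
* **Initialization.** Codebook rows are drawn with replacement from the
  gene profiles (seeded). Data-sampled initialization keeps the first BMU
  searches meaningful without a PCA step.
* **Training.** Online Kohonen updates for `100 × n_units` steps (43,700 at
  default size). Profiles are presented cyclically in a seeded shuffled
  order. The update is `w ← w + α(t) · h(t) · (x − w)` for every unit, with
  Gaussian neighborhood `h = exp(−d²/2σ²)` on Euclidean grid distance.
  Learning rate decays linearly 0.05 → 0.01, the neighborhood width σ
  linearly from `max(rows, cols)/2` to **0.5**. The small terminal σ
  matters: with σ = 1 the nearest neighbors still receive 61% of each
  update at the end of training, the codebook smooths toward the global
  mean and the final quantization error can exceed the initial one; at
  σ = 0.5 the late phase is effectively winner-take-all vector
  quantization, training reliably lowers quantization error, and topology
  preservation is unaffected (verified on clustered data, 10/10 seeds).
  A batch (assign-then-average) mode is available behind `mode="batch"`;
  online is the default.
* **Assignment.** BMU by Euclidean distance (`scipy.spatial.distance.cdist`,
  which is exact for coincident points); ties break toward the lowest node
  ID. The tie rule is only observable on constructed inputs but makes the
  pipeline bit-reproducible.

The map is a `SelfOrganizingMap` estimator (fit / predict / transform,
`labels_`, `codebook_`) and composes with scikit-learn tooling.

## Tatami aggregation and gene selection

Node transcription values pool all (gene, replicate) cells of a node under
one condition; with equal replicate counts this equals the mean of per-gene
means, and the gene-count-weighted node means re-aggregate exactly to the
global mean (tested to 1e−9). Empty nodes are NaN in transcription maps and
0 in secretion maps, and are excluded from selection and percentile
computations.

"Highly transcribed" is a **node-level** property with strict inequalities
on both sides (> threshold in SSF, < threshold in control); a node exactly
at the threshold belongs to neither set. Genes inherit their node's status.
Secretome protein IDs resolve to genes by string equality; unmatched IDs
are logged and excluded, never fatal. Each detected protein contributes one
count to the map of every time point at which it was detected.

Connected clusters of selected nodes use `scipy.ndimage.label` with
8-connectivity by default (4-connectivity available); "neighboring" on a
grid is ambiguous and 8-connectivity is the more permissive reading.

## Correlation and lag

Spearman's ρ (average ranks) between node-wise transcription and node-wise
secretion counts for every time-point pair, dropping gene-less nodes
pairwise; p-values from the large-sample t approximation, with an exact
permutation option for ≤ 12 usable nodes. Both gene-set variants are always
computed: all genes, and the secreted subset (node means recomputed over
predicted-secreted genes only; when no annotation is supplied, the genes
matched by secretome IDs stand in). The lag summary compares, per
transcriptome time *j*, `max_{i>j} ρ(i, j)` against `ρ(j, j)`.

## Synthetic data

The generator emulates the study conditions the analysis assumes: 2,000
genes, 4 conditions (control culture plus SSF days 4/10/15) × 3 replicates,
negative-binomial counts with shared dispersion 0.05 (Poisson limit at 0),
and five planted profile classes (early 10%, core 12.5%, late 10%,
control-high 5%, flat 62.5%). High states sit at 14 log2 and baselines at
7–8 log2 — a ≥ 4-log2 separation straddling the 12-log2 threshold, as a
clear induction in RNA-seq data would. The full-scale genome (~18k genes)
runs in minutes but the default keeps tests in seconds.

20% of genes are flagged secreted. Detection at SSF time *t* is Bernoulli
with `p = logistic(−12 + 1.0 · m)` where *m* is the gene's mean log2
expression **one condition earlier** (`lag_steps=1`): p ≈ 0.007 at
baseline, ≈ 0.88 at the high state. Times before the first SSF point fall
back to the control-culture mean — the pre-induction state — rather than
clamping to the first SSF value; clamping would make first-time-point
detections statistically identical to the lag-free case and erase the very
lag the layer exists to plant. The lag is expressed in condition index, not
days, and its magnitude is a modeling choice, not an inference.

What passing the recovery tests shows: under well-separated planted means
and low dispersion, the full pipeline (normalization → SOM → node selection)
returns the planted core module with precision and recall ≥ 0.9 and
profile-class ARI > 0.7, and reproduces the lag ordering of the correlation
matrix in ≥ 9/10 seeds. What it does not show: performance on real data
with continuous effect sizes, gene-specific dispersions, library-size
imbalance or partially induced modules — the generator plants none of
these.

## Selectivity arithmetic

Component loss is the standard mass balance
`100 · (m₀x₀ − m_f x_f)/(m₀x₀)`; gains return negative losses with a
warning. L/C and L/H are computed at full precision and additionally
reported rounded half-up to 2 decimals, matching how printed composition
tables round; zero or missing denominators yield NaN ("ND"). Conversion
yields use anhydro factors 0.9 (hexose → glucan) or 0.88 (pentose). The
ratios are dimensionless and scale-invariant (property-tested).

## Determinism and problem sizes

Every stochastic step (truth generation, counts, secretome, SOM
initialization and presentation order) takes an explicit seed; the whole
pipeline is bit-reproducible per seed. Default test and benchmark sizes —
2,000 genes × 12 libraries, 437-unit map, 43,700 training steps — complete
in a few seconds each; the acceptance script's full run is under a minute.

## Known limitations

* The SOM's grid shape, topology, neighborhood, schedules and
  initialization are declared package defaults; headline node IDs from any
  particular published map depend on choices a reimplementation cannot
  recover.
* Spearman p-values are approximate under heavy ties unless the
  permutation option is used.
* The secreted-subset correlation variant silently degrades to
  secretome-matched genes when no predicted-secreted annotation is given.
* Carried annotation columns (CAZy family, functional labels) are passed
  through, not statistically tested.
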