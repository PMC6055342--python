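# tatamisom

Self-organizing-map "Tatami maps" for integrating a time-course
transcriptome with secretome detections, plus the biomass mass-balance
arithmetic used to quantify selective delignification.

## The problem

White-rot fungi grown on lignocellulose (e.g. wheat straw under solid-state
fermentation, SSF) remodel their transcriptome within days and secrete
successive waves of carbohydrate- and lignin-active enzymes. Two questions
recur in such studies:

1. **Which co-regulated gene modules drive each phase of the culture**, and
   how do they relate to the proteins actually detected extracellularly —
   including the lag between a transcription peak and the corresponding
   secretome signal?
2. **How selective is the delignification**, i.e. how much lignin is removed
   per unit of cellulose or holocellulose consumed?

`tatamisom` addresses both with a compact, fully tested pipeline intended
for analysts working with gene × sample count tables and per-time-point
protein detection lists; no read-level data are touched.

## The method

* **Normalization.** Raw counts are scaled by *median-of-ratios* size
  factors: for library *j*,
  `s_j = median_g ( K_gj / (∏_k K_gk)^(1/n) )`
  over genes with a positive count in every library, then transformed to
  `log2(K_gj / s_j + 1)`.
* **A single master SOM.** Each gene's feature vector is its normalized
  log2 expression across *all* replicate libraries. A Kohonen map on a
  19 × 23 rectangular grid (437 units, node IDs 1–437 row-major) is trained
  online for 100 iterations per unit — 43,700 sequential updates with a
  Gaussian neighborhood and linearly decaying learning rate and radius.
  Each gene is assigned to its best matching unit (BMU, Euclidean).
* **Tatami maps.** Per node: mean log2 transcription per condition, and the
  count of secreted proteins detected per time point. A node with mean
  transcription > 12 log2 (≈ the upper quartile of gene-condition means)
  marks its genes *highly transcribed*; genes in nodes high at an SSF time
  point **and** low (< 12) in the control culture form condition-specific
  sets, whose intersection over all SSF time points is the *core set*.
  Selected nodes are grouped into grid-connected clusters (8-connectivity).
* **Integration.** For every (secretome time *i*, transcriptome time *j*)
  pair, Spearman's ρ between node-wise secretion counts and node-wise mean
  transcription; a transcription→secretion lag shows up as
  `max_{i>j} ρ(i, j) > ρ(j, j)`.
* **Selectivity.** From component losses, `L/C = lignin loss / cellulose
  loss` and `L/H = lignin loss / holocellulose loss`; carbohydrate net
  conversion yield is `100 · released sugar · anhydro factor / carbohydrate
  content`.

A seeded synthetic-data generator (negative-binomial counts over planted
early / core / late / control-high / flat modules, and a logistic,
one-step-lagged secretome layer) provides ground truth for recovery tests.

## Worked example

```python
>>> import tatamisom as ts
>>> counts, meta, secretome, truth = ts.simulate_dataset(seed=1)
>>> res = ts.analyze(counts, meta, secretome, ts.RunConfig(seed=1))
>>> res.som.total_iterations_
43700
>>> len(res.gene_sets.core)          # genes high at D4, D10 and D15, low in control
250
>>> res.correlations["all-genes"].rho.round(2)
transcriptome    D4   D10   D15
secretome
D4            -0.11 -0.06 -0.01
D10            0.53  0.28  0.25
D15            0.27  0.51  0.52
>>> bool(res.lag.lagged["D4"])
True
```

The Day-4 transcriptome correlates far better with the Day-10 secretome
(ρ = 0.53) than with the concurrent one (ρ = −0.11): the planted one-step
secretion lag is recovered from the node-level maps. The 250 recovered core
genes are exactly the planted core module.

The selectivity arithmetic runs off any composition-loss table; a reference
wheat-straw table is bundled:

```python
>>> from tatamisom.io import load_wheat_straw_composition
>>> from tatamisom.selectivity import selectivity_table
>>> selectivity_table(load_wheat_straw_composition())[["label", "lc", "lh"]]
     label    lc    lh
0  Control   NaN   NaN
1    Day 4   NaN   NaN
2   Day 10  1.84  1.81
3   Day 15  2.08  2.29
```

An L/C above 2 after 15 days means lignin is being removed twice as fast as
cellulose — strongly selective delignification.

Every stage is also exposed on the command line
(`tatamisom simulate | normalize | train-som | tatami | correlate |
selectivity | run-all`); `run-all` writes every result table plus the
resolved YAML config into a run directory, bit-reproducibly for a fixed
seed.

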