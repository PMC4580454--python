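# Methods

## The analysis model

The pipeline treats a diurnal transcriptome experiment as a gene ×
time-point matrix of FPKM values over an ordered design of T collection
points, each labelled with its phase (light/dark) and hour within phase.
The reference design is 7 points over a 12 h : 12 h photoperiod —
D6, D10, L1, L4, L6, L10, D1 — and the order of the design file is
authoritative everywhere a profile is walked (consecutive differences,
ramp checks, peak ties).

### Gene selection: MeanNeighbor

For a profile x of length T,

    MeanNeighbor(x) = (1/(T−1)) · Σ_{t=1..T−1} |x_{t+1} − x_t|.

There is no wraparound term |x_1 − x_T|: the sum runs over the T−1
consecutive gaps only. The statistic is computed on raw FPKM, so it is
invariant to additive shifts but scales linearly with the profile — it
deliberately conflates expression magnitude with temporal variability and
therefore implements "highly expressed AND strongly changing" as a single
score. No separate expression floor or pre-filter is applied. Ranks are
assigned by descending score with ties broken by ascending lexicographic
gene id; selection takes the top n (default 1000) as a prefix of that
ranking, which makes the selected set independent of input row order.

A consequence worth knowing: in a population whose baseline expression
spans orders of magnitude, a highly expressed but temporally flat gene can
outscore a lowly expressed strongly cycling one. On the synthetic study at
its default baseline spread (log-sd 1.0) roughly a third of the selected
genes are high-baseline background genes; the truly cycling genes that are
selected still cluster essentially perfectly (see the acceptance report).
This is the behaviour of the statistic, not an artifact of the
implementation.

### Normalization

Each selected row is transformed to (x_t − mean(x)) / sd(x) with the
*sample* standard deviation (denominator T−1, matching R's `sd`, the
environment in which this style of analysis is conventionally run).
Zero-variance rows cannot be normalized and are excluded with a logged
warning. The "relative level between −3 and +3" used for heatmap display
is implemented as clipping of the z-profiles; it is display-only and, for
T = 7, vacuous, since the largest |z| attainable under sample sd is
(1 − 1/T)·√T ≈ 2.27.

### Clustering

Agglomerative clustering with the Ward criterion on Euclidean distances
between z-profiles, computed via `scipy.cluster.hierarchy.linkage`. The
default variant `d2` is the textbook minimum-variance method (the
Lance–Williams coefficients applied to squared distances, heights on the
distance scale, R's `ward.D2`). The `d` variant applies the same
coefficients to unsquared distances (R's `ward.D`); it is obtained by
feeding the recurrence square-rooted distances and squaring the reported
heights, which reproduces `ward.D` merges and heights exactly. Merge
heights are non-decreasing in either variant, and duplicate rows merge at
height zero before anything else. Determinism comes from scipy's
nearest-neighbor-chain algorithm being deterministic for a fixed input
order; a bespoke tie-breaking rule was considered and dropped as redundant
for that purpose. The tree is cut into K groups (default 7) and labels
1..K are assigned by first appearance along the dendrogram leaf order, so
groups read top-to-bottom on a heatmap.

K is a configuration input; no data-driven choice of K (gap statistic,
silhouette) is attempted, since the analysis this package reproduces fixed
K by inspection of the dendrogram.

### GO-term overrepresentation

For each group and each term annotated to at least one group member, a
2×2 table (a, b; c, d) is formed against a background universe and the
one-sided overrepresentation p-value P(X ≥ a) of the hypergeometric
distribution with the table's margins is computed through
`scipy.stats.hypergeom.sf`, exact for margins well beyond 1e5. Choices:

* **One-sided by default.** Only overrepresentation is asked; a two-sided
  Fisher test is not what the bar charts report.
* **Background universe**: all genes in the expression matrix by default —
  unannotated genes count among the term-negative cells, reflecting that
  most genes in a de novo annotated genome carry no GO terms. The
  `annotated` convention restricts the universe (and the groups) to
  annotated genes; counts, tests and percentages always use one universe
  consistently.
* **Cutoffs**: raw p ≤ α (default 0.05) with no multiple-testing
  correction by default, mirroring the analysis style this reproduces.
  If a group yields more than `overflow_threshold` (default 100)
  significant terms, significance is re-assessed at `strict_alpha`
  (default 1e−7) and the applied cutoff is recorded in provenance and in
  every output row. Benjamini–Hochberg adjustment is available behind
  `--fdr`.
* **Flat terms**: GO identifiers are opaque labels; no DAG ancestor
  propagation is performed, as no propagation procedure is part of the
  reproduced method.

### Temporal patterns

Per gene: peak = argmax (ties to the earliest design point), trough =
argmin, fold change = (max + ε)/(min + ε) with pseudocount ε = 0.01 FPKM
(negligible against typical FPKM scales of 8–1500, but makes zero troughs
well-defined), and a pattern class:

* `dark_to_dawn_peak`: peak at D10 or L1 and fold ≥ `min_fold`;
* `late_light_peak`: peak at L4/L6/L10, fold ≥ `min_fold`, and
  non-decreasing from L4 through the peak allowing at most one down-step
  ("gradual increase" made decidable); a peak at L4 itself satisfies the
  ramp trivially;
* `other`: everything else, including near-flat profiles.

`min_fold` defaults to 2, the lower end of the modest (2–4×) fold range
of the late-light class. For designs without the standard labels, the
label sets are passed explicitly.

## Synthetic data generator

The generator emulates the reference study: K groups (default 7) of
`genes_per_group` genes (default 100) plus `n_background` flat genes
(default 4300, giving 5,000 total), over the 7-point design. Group g uses
a deterministic unit-variance template z_g — a peak at one time point for
the first T templates, rising/falling ramps beyond — and gene i in group g
gets

    FPKM_t = b_i · exp(amplitude · z_g(t) + ε_{i,t}),

with b_i log-normal (median 50 FPKM, log-sd 1.0 — order-of-magnitude
realistic for bulk FPKM), amplitude 0.8 (≈ 8-fold peak-to-trough for peak
templates), and ε i.i.d. normal with sd 0.2 on the log scale.
Multiplicative log-normal noise keeps values strictly positive and makes
noise proportional to expression, as FPKM noise is. Background genes have
amplitude 0. In the noiseless limit the z-scored *log* profile of a group
member equals its template exactly (the construction is multiplicative, so
the identity holds on the log scale). Designed pattern classes are derived
from template structure alone (peak label, amplitude-driven fold), giving
exact ground truth for the pattern tests.

Annotations: every gene draws `terms_per_gene` (default 3) distinct terms
uniformly from a vocabulary of 200; each group additionally has one
planted term assigned to members with probability 0.5 and to non-members
with probability 0.05. All draws are reproducible from the configuration
seed (annotations use a fixed offset of the expression seed so the two are
independent draws of one configuration).

What the generator does **not** emulate: library-size or gene-length
biases, count-level (Poisson/NB) noise at low expression, correlated noise
across genes, partially overlapping or unequal-size groups, and the GO
DAG's term-term correlations. Passing tests therefore demonstrate the
pipeline's correctness and its recovery behaviour under clean planted
structure, not performance guarantees on real data.

## Problem sizes and numerics

The test suite and the acceptance script run the full default study
(5,000 genes × 7 points), 20-replicate recovery benchmarks at 700 genes,
and a 200-replicate null calibration at 100 genes per replicate; all
complete in seconds on one CPU. Tolerances: oracle equality for the
MeanNeighbor and Fisher computations at 1e−12; normalization invariants at
1e−9; recovery thresholds (ARI ≥ 0.90, ≥ 95% planted-term recovery, ≥ 90%
pattern recovery at noise sd 0.2) follow the generator's default
conditions. Degenerate inputs are handled explicitly: flat rows are
excluded from normalization, a = 0 tables return p = 1 exactly, zero
troughs require a positive pseudocount, and peak ties resolve to the
earliest time point.

## Known limitations

* MeanNeighbor's magnitude-variability conflation (above) means selection
  purity depends on the baseline expression spread of the population.
* The heatmap itself (diverging palette over the clipped z-profiles) is
  left to standard plotting tools on `relmatrix.tsv`/`clusters.tsv`; the
  package ships the matrices, not the figure.
* GO enrichment inherits every caveat of raw-p Fisher testing with flat
  terms: no FDR control by default and no term dependence modelling.
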