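# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical decisions a user should know before trusting the output.

## Zymography

Calibration is ordinary least squares of observed grey value on known
activity over ≥ 2 standards with distinct activities; the curve is
inverted per pixel, and negative activities (grey below the intercept,
i.e. below the blank) are clamped to zero with the clamped-pixel count
kept on the result. Hotspots are pixels *strictly* greater than
`mean + 2·SD` of the ROI grey values. Conventions fixed here:

- **SD is the sample standard deviation (ddof = 1).** The choice is
  immaterial for large ROIs but is pinned for reproducibility and
  recorded in every output.
- **%hotspot area divides by the total ROI pixel count**
  (`N_hot + N_background`). A formula with the denominator
  `N_hot − N_background` circulates in print; it can be negative and is
  treated here as a sign typo. `detect_hotspots(..., eq1_as_printed=True)`
  reproduces the literal form for audit.
- The rule is affine-equivariant: rescaling grey values with any positive
  affine map leaves the hotspot mask and %area unchanged (property-tested).

Compartments: rhizoplane = the root footprint mask (assumed already
registered to the membrane — registration is out of scope and the mask is
an input); rhizosphere = chessboard (8-connected) morphological dilation
of the footprint by `band_width_px` minus the footprint; background = the
remaining ROI. The band width has no agreed field value and must be
chosen by the user (default 3 px in the pipeline). Per-compartment
hotspot thresholds can be *local* (recomputed within the compartment,
default) or *global* (whole-ROI threshold applied everywhere); both are
reported because published workflows are ambiguous on this point. Empty
compartments report NaN, never 0.

## Community statistics

- Rare-taxon filter: a taxon is kept iff its overall relative abundance
  (taxon total / grand total × 100) is **≥** the threshold (default
  0.005%); the boundary is inclusive, a convention we fix because "remove
  below a threshold" leaves the boundary case open.
- Shannon diversity uses natural log (nats).
- Bray–Curtis is computed on relative abundances by default (raw counts
  optional); pairs of all-zero samples are an error, not a silent 0/0.
- PERMANOVA follows Anderson's sum-of-squares partition of the
  (squared) distance matrix; pseudo-F is cross-checked against
  scikit-bio's implementation in the tests, and the permutation p-value
  uses the add-one convention `p = (1 + #{F* ≥ F}) / (1 + n_perm)` so it
  is never exactly zero. Note the attainable type-I level at α with
  n_perm = 199 is 9/200 = 0.045, which the calibration tests use.
- Differential abundance is a two-sided Wilcoxon rank-sum on relative
  abundances per taxon with Benjamini–Hochberg q-values (statsmodels).
  The test is deliberately simple and rank-based; count-model
  alternatives (e.g. negative-binomial GLMs) are out of scope.

## Co-occurrence networks

The screen computes all pairwise Spearman correlations (Pearson
optional) with two-sided p-values from the t-approximation on n−2
degrees of freedom — the convention of Hmisc::rcorr, kept for
comparability. At n = 6 the approximation deviates from the exact
rank-permutation null by at most ≈ 0.05–0.08 absolute (measured; the
exact-enumeration test documents 0.08). Zero-variance taxa are excluded
with a log entry. Edges require raw p < 0.01 (no multiple-testing
correction by design — a BH option exists); negative correlations form
edges with their sign kept as an attribute, and degree counts both
signs. Isolated nodes are dropped by default so node counts refer to
connected genera.

Topology: unnormalised betweenness, global transitivity, mean shortest
path over *connected* pairs only (thresholded correlation graphs are
routinely disconnected), and modularity of the seeded-Louvain partition.
All metrics are test-verified against brute-force shortest-path
enumeration oracles.

Null models: uniform G(n, m) with the observed node and edge counts
(degree-preserving rewiring available as an alternative, since "same
nodes and edges" does not pin the ensemble down). Per-metric two-sided
empirical p-values with the add-one convention; the *non-random* verdict
fires when any metric in the configured list has p < 0.05. Because an
any-metric verdict over several correlated metrics has no clean nominal
level, the self-null calibration experiments use a single metric
(clustering), for which the attainable two-sided level with 99 nulls is
≈ 4%.

Hubs are the k = 10 highest-degree nodes; ties break by betweenness,
then lexicographic label, deterministically, and tie events crossing the
k-th place are logged. The hub-shift sets satisfy
|maintained| + |lost| = |maintained| + |gained| = k by construction.

## Modules and trait associations

Module detection is networkx Louvain with a fixed seed on the unweighted
graph; modules are ranked by size (ties by summed degree, then smallest
member label) and relabelled densely from 1, with the top 4 carried into
association analysis by default. The single-edge graph is pinned by test
to yield one two-node module.

The module → sample bridge is the mean of member genera's z-scored
relative abundances (an eigen-profile would be the natural alternative;
the mean is transparent and robust at small n). Associations are
Spearman correlations with two-sided p-values, significant at p < 0.01,
with pairwise-complete deletion of missing trait values. Mantel tests
(Pearson correlation of off-diagonal entries, simultaneous row/column
permutation, add-one p) confirm matrix-level structure; the pipeline
default compares Euclidean distances of module profiles against
Euclidean distances of trait vectors. The confirmation rule treats an
association as supported at Mantel p < 0.01 and r > 0.4 — a published
variant quotes "r > 4", which is impossible for a correlation and is
read as a misprinted 0.4; both thresholds are configurable.

Untreated/treated module identity is established by greedy
maximum-Jaccard matching of member sets (matching scores are reported);
shift classification is then pure set algebra on the significant
(module, trait) pairs: new = treated-only, maintained = both, missed =
untreated-only.

## Synthetic generator

What it emulates: genus-level 16S count tables with block-structured
co-occurrence (latent factor per module per sample; member log-mean =
baseline + coupling × loading × factor; negative-binomial counts with
variance μ + dispersion·μ²), traits linearly coupled to chosen module
factors plus Gaussian noise, and zymogram membranes as a branching
random-walk root footprint with elevated hotspot patches on Gaussian
background. Defaults mirror one condition of a rhizobox study: 9 samples,
~180 genera, 4 modules, dispersion 0.5, baseline mean ≈ 50 counts.
Recovery and power experiments use 50 samples, where coupling 2 gives
near-certain edge detection at p < 0.01.

What it does not emulate: compositional sequencing depth variation,
taxonomic assignment error, the full two-site × two-compartment factorial
with its real effect sizes, rhizobox pseudo-replication (the generator
assigns one rhizobox per sample so trait n equals sample n — real designs
with 3 boxes × 3 subsamples have fewer independent trait units), membrane
optics, or spatially correlated image noise. Passing recovery tests
therefore demonstrate that the estimators do what they claim under a
known truth, not that real studies have comparable power.

One consequence worth knowing: relative-abundance normalisation induces
negative correlations between modules (when one module booms the others'
shares shrink), so null traits can pick up weak spurious associations in
small samples. This is a property of compositional data, not a bug, and
is visible in the pipeline demonstration.

## Pipeline and problem sizes

The pipeline simulates two arms (untreated/biochar) of one
site × compartment condition and runs all stages. Demonstration sizes are
24 samples × 60 genera per arm, 199 permutations/null graphs, 96×96 px
images — small enough to run in seconds while keeping every stage's
behaviour representative; the acceptance script scales individual
experiments (200 null simulations, 1000 algebra trials, 10–25 recovery
seeds) the same way. All stage seeds derive deterministically from the
single config seed, and rerunning a config reproduces every numeric
artifact byte-for-byte (tested).

## Known limitations

- Correlation networks on relative abundances are not compositional
  network inference (no SparCC/SPIEC-EASI); this is deliberate scope.
- The Spearman screen's t-approximation is anti-conservative at very
  small n; below ~7 samples per condition, treat edge p-values as
  approximate (the exactness tests quantify this).
- Mantel and PERMANOVA p-values are permutation-based and inherit the
  granularity 1/(n_perm + 1).
- Module matching by Jaccard can be ambiguous when detected modules are
  unstable; the reported matching scores should be inspected before
  interpreting shift classifications.
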