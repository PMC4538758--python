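# Methods

This note records the models, conventions and defaults behind `sscskin`, and
what the synthetic-data tests do and do not demonstrate.

## Preprocessing model

Two-channel arrays measure a sample (Cy3) against a common reference (Cy5).
Analysis is done on log₂(Cy3/Cy5); raw scanner ratios arrive as
log₂(Cy5/Cy3) and are negated exactly once (`orient_ratios` refuses to run
twice, so a double flip cannot occur silently).

* **Lowess normalization** (optional stage): per sample, M = log₂(ch1/ch2)
  is regressed on A = ½·log₂(ch1·ch2) with a robust locally weighted fit and
  the trend subtracted. Defaults: window fraction 0.3, 3 robustness
  iterations — conventional values for MA-plot normalization. A constant M
  is removed entirely (zero-bias fixed point); A values are untouched. When
  A is degenerate (a single intensity level) the fit falls back to the
  median of M.
* **Background filter**: a probe is kept in a sample when Cy3 ≥ 1.5× its
  local Cy3 background *or* Cy5 ≥ 1.5× its Cy5 background, boundary
  inclusive. Failures become missing values; probes failing everywhere are
  dropped. The OR combination reflects that a real signal in either channel
  makes the ratio informative.
* **Missing-data filter**: rows with strictly more than 20 % missing entries
  are removed; a row at exactly 20 % is kept.
* **KNN imputation** (k = 10): row-to-row distance is the root-mean-square
  difference over columns observed in both rows, which keeps rows with
  different missingness patterns comparable. A missing cell takes the mean
  of the k nearest rows observed at that column; if no candidate neighbor
  exists the row mean is used and logged. Observed values are never altered.
* **Probe collapsing**: probes map to gene symbols (uppercased everywhere on
  ingestion) and multi-probe genes take the per-sample maximum; a median
  mode is available. Max favors the best-hybridizing probe and is the common
  default of collapse utilities.
* **Median centering**: each gene row minus its median (mean of the two
  middle values for even lengths); idempotent and order-preserving.

The matrix carries a stage marker and the stage functions refuse to run out
of the canonical order (filter → orient → missing filter → impute → collapse
→ center), so downstream modules can rely on a fully processed input.

## Responder statistics

An **improver** has a strictly > 20 % MRSS decrease from baseline at
12 months; the boundary case (exactly 20 %) is a non-improver. Group change
summaries report the mean per-patient change in points and the percent
change computed on group means — the convention that reproduces published
trial-level summaries — while classification is strictly per-patient.
Display rounding is one decimal for points and nearest integer for percent.

The subset-by-response association uses the Pearson χ² on the 2×2 table
(fibroproliferative vs other) × (improver vs non-improver) with 1 df and no
continuity correction; with the continuity correction the test loses exact
agreement with the standard uncorrected form on small tables, so the
correction is off. Zero margins leave the test undefined and raise.

Signature trends across the four (response × visit) groups use one-way
ANOVA followed by Tukey HSD with a single pooled variance; Tukey p values
are never smaller than the unadjusted pairwise p (property-tested).

## Marker selection

Unpaired comparisons use the Welch t statistic with Satterthwaite df by
default (a pooled-variance variant is a flag); paired comparisons use
t = mean(d)/(sd(d)/√n) on post-minus-baseline differences, df = n − 1.
P values are two-sided and parametric. No multiplicity correction is applied
at the gene level — with a handful of arrays per class such correction is
hopeless, and the pathway-level statistics carry the multiple-testing
burden. Degenerate rows are totalized: zero spread with zero difference
gives t = 0, p = 1; zero spread with a nonzero difference gives the
machine-minimum p and a `degenerate` flag.

## Enrichment

**Ranking**: signal-to-noise (meanA − meanB)/(sdA + sdB), each sd floored at
max(0.2·|class mean|, 0.2); a Welch-t metric is available. Ties break by
gene symbol so orderings are reproducible.

**ES**: walking the ranked list, set members add |score|^w (w = 1 by
default) normalized by the total hit weight; non-members subtract
1/(N − N_hits). The ES is the signed maximum excursion, bounded in [−1, 1].
With w = 0 the statistic reduces to the classical two-sample
Kolmogorov–Smirnov statistic between hit and miss rank positions
(property-tested against an independent KS routine). When every hit weight
is zero the hits fall back to uniform weights.

**Null model**: *gene-set* permutation — random same-size sets drawn from
the ranked list — because with two to four samples per class phenotype
permutation has essentially no support. Defaults: 1,000 permutations,
set-size window [15, 500]. NES divides ES by the mean of its same-sign null
ES; nominal p is the same-sign null tail fraction. FDR q is the
ratio-of-tails estimate on the pooled normalized null, positive and negative
branches separate, with q(set) taken as the minimum estimated FDR over
thresholds that include the set. When the ranking is completely flat the
normalized null is undefined; all sets then report NES = 0, p = q = 1.
Permutation ES values are computed from sorted hit positions only (the
running sum is piecewise linear between hits, so its extremum lies at one of
2k candidate points), which makes the permutation loop vectorizable; the
equivalence with the explicit running sum is tested exhaustively on all
subsets of 8-gene lists.

**ssGSEA**: per sample, genes are ranked by expression (symbol-broken ties)
and position i of N gets weight (N − i + 1)^α, α = 0.75 by default; the
score *integrates* the cumulative normalized hit weight minus the cumulative
miss fraction over the whole list (the integrated-difference variant; α = 0
recovers an unweighted reference implementation exactly). Scores are
comparable across samples only after dividing the whole matrix by its
maximum score (idempotent; a non-positive maximum is an error because the
scaling would flip orientation).

**Core enrichment**: members at or before the running-sum peak (positive ES)
or at or after the trough (negative ES).

## Intrinsic subsets

Centroids are per-gene means over the reference samples of each subset
(fibroproliferative, inflammatory, normal-like; the limited subset is not
modeled because no limited-SSc samples occur in this setting). A sample is
assigned to the centroid with the highest Spearman ρ (average-rank ties;
two-sided p from the t approximation t = ρ√((n−2)/(1−ρ²)), adequate at the
hundreds of genes involved). The "lowest p" is checked for concordance
rather than used as a second key: for fixed n, p is monotone in |ρ|, so the
two criteria can disagree only when a negative ρ has larger magnitude —
such samples are flagged and logged, not silently reassigned. Assignment is
invariant under strictly monotone transformations of the sample vector
(rank-based; property-tested).

Clustering of genes and arrays uses 1 − uncentered correlation
(Σxy/√(Σx²·Σy²), i.e. cosine similarity without mean subtraction) with
average linkage, verified against an O(n³) naive agglomeration on small
fixtures.

## Synthetic-data generator

The generator emulates a small paired-biopsy trial; its defaults are the
standard study conditions used by the tests:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 1,500 | genes on the array (desk-scale stand-in for ~18k) |
| `n_patients` | 12 | two samples each (baseline, 12-month post) |
| `improver_fraction` | 0.5 | Bernoulli improver assignment |
| `centroid_effect` | 2.0 log₂ | shift of the 60-gene marker block per subset |
| `treatment_effect` | 1.5 log₂ | improver baseline elevation and post-treatment drop of the active sets |
| `noise_sd` | 0.4 log₂ | gene-wise additive Gaussian noise |
| `missing_rate` | 0.02 | per-entry missingness |
| `background_level` | 100 | log-normal local background scale |
| `subbackground_rate` | 0.01 | probes pinned below the 1.5× filter |
| `two_probe_fraction` | 0.10 | genes carrying a redundant second probe |

Subset structure: each of the three subsets — including normal-like — has
its own marker block shifted by `centroid_effect` in carriers at both
visits. Giving normal-like a positive block (a "normal skin program")
rather than a flat profile is deliberate: a flat profile would leave its
samples with no rank signal and make Spearman assignment undefined noise.
The active sets are sized 19 (TGFBR-like) and 50 (PDGFRB-like), the typical
leading-edge sizes of receptor-signaling signatures; decoy sets of matched
sizes are drawn from unshifted genes.

Intensities are back-computed from the target log ratios around a geometric
mean of at least ~2.8× background, so every expressed probe clears the 1.5×
filter through at least one channel; sub-background probes are pinned at
1.2× background in both channels and are the known truth set of the filter.
Noise is additive Gaussian on the log ratio at the probe level
(homoscedastic) — the simplest model consistent with log-scale analysis.

MRSS trajectories interpolate linearly from baseline (N(30.1, 8.2) clipped
to [16, 51]) to a 12-month target whose percent decrease is drawn U(25, 50)%
for improvers and U(−10, 15)% for non-improvers; 1 point of Gaussian noise
is placed on the interim visits only, so the > 20 % rule recovers the
planted labels deterministically while the visit series still looks noisy.

What passing recovery tests show: under well-separated conditions
(centroid effect 5× the noise sd) the pipeline recovers planted subsets,
flags the planted gene sets and tracks treatment dynamics. What they do not
show: behavior under dye-bias curvature, intensity-dependent dropout,
spatial artifacts, probe-specific affinity differences, or subset
proportions and effect sizes different from the configured ones — the
generator does not model these.

## Numerical and design choices

* All randomness flows from integer seeds through `numpy`'s Generator;
  per-stage substreams (`default_rng([seed, stage])`) let stages be
  regenerated in isolation. Two runs of the CLI `all` command with one seed
  produce byte-identical artifact trees (checksummed in `manifest.tsv`).
* GCT/CLS/GMT/PCL readers accept Unix and Windows line endings; missing
  tokens on read are empty/`NA`/`NaN` (case-insensitive), written back as
  the empty field. PCL support is read-only — GCT is the internal canonical
  carrier, so a PCL writer would only duplicate it.
* Gene symbols are uppercased at every ingestion point so matrices,
  annotations and gene sets agree on membership.
* Floats are serialized with `repr` (GCT) or `%.10g` (tables): enough
  digits for exact round-tripping or stable checksums respectively.
* Test problem sizes (1,500-gene simulated studies, 8-seed recovery
  batches, 1,000-gene null calibrations, ≤ 8-item exhaustive oracles) were
  chosen so the full suite exercises every path in seconds while keeping
  binomial test bounds meaningful.

## Known limitations

* The lowess stage is optional and not part of the enforced order; on
  back-computed synthetic intensities the M–A trend is flat by construction,
  so the stage is exercised by unit fixtures rather than the end-to-end run.
* Welch vs pooled variance for small-subgroup t tests can matter at n ≤ 4;
  both are exposed, Welch is the default.
* The ssGSEA score is the integrated-difference variant; a maximum-deviation
  variant is not implemented.
* Phenotype-permutation GSEA is out of scope (and statistically unsupported
  at these sample sizes).
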