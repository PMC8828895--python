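# Methods

## The filtering cascade

A candidate interaction is a (bait, prey, method) triple with an average
spectral count — the arithmetic mean of the prey's PSM counts over all of
the bait's replicate runs for that method, substituting 0 in runs where
the prey is absent — and a confidence score in [0, 1]. Biological and
technical replicates are pooled into one average: the distilled table
carries a single abundance per edge, and the replicate classes are
instead compared in QC.

The cascade applies two stages in order, and records exactly one decision
per input:

* **Score cutoff** (`saint_cutoff`, default 0.74): kept iff score ≥
  cutoff. The boundary is inclusive, following the convention that a
  reported cutoff describes the kept set; `saint_inclusive=False` flips
  it.
* **Contaminant rules**, driven by the prey's repository profile
  (frequency *f* = n_detected/n_experiments, average count *a*):
  * BioID: dropped if *f* ≥ `freq_high` (0.50); else dropped if
    `freq_mid` ≤ *f* < `freq_high` (0.25–0.50) and *a* exceeds the study
    average; else kept.
  * AP-MS: if *f* > `freq_high`, kept only if study average ≥
    `apms_fold` × *a* (3.0, inclusive); otherwise kept.

Boundary conventions where prose thresholds are ambiguous at equality:
BioID drops at exactly 50 % ("lower than 50 % allowed" read strictly),
the mid band is half-open [0.25, 0.50) so the two BioID rules cannot
overlap, the AP-MS trigger is strict (*f* > 50 %), and the fold test is
inclusive, so a repository average of 0 passes trivially. Each convention
is a config flag (`bioid_drop_at_freq_high`, `apms_fold_inclusive`).
Preys missing from the repository table get an implicit (0, 716, 0.0)
entry: absence from a contaminant repository is evidence of
non-contamination.

## The surrogate scorer

When an externally scored table is unavailable, `surrogate_score` maps
each prey to

    score = b^2 / (b^2 + (c + 1)^2)

with *b* the bait-side average count and *c* the maximum count observed
for that prey in any control run of the same method. This is not a
probabilistic model — it is a deliberately simple monotone statistic
(increasing in *b*, decreasing in *c*, exactly 0 at *b* = 0, → 1 as
*b* ≫ *c*) whose only job is to make the cascade executable end-to-end
from runs and controls. The +1 regularizes preys never seen in controls;
the squaring sharpens the transition around *b* ≈ *c* so that the default
0.74 cutoff corresponds to *b* ≳ 1.7 (c + 1). For real data, scores from
a dedicated scorer should be supplied via the SAINT-style reader.

## Quality control

Replicate agreement is Pearson's *r* between the count vectors of each
unordered pair of a bait+method's runs, built over the union of the two
runs' preys with zeros for absences — in count data, a prey detected in
one replicate but not the other is disagreement, not missing data.
Constant vectors make the correlation undefined and raise an error at the
single-pair level; the batch report skips such pairs. Counts are used
raw by default; a `log1p` option compresses dynamic range.

## Network summaries

Edges are directed bait → prey; pair identity for method overlap and
known/novel comparisons is the undirected gene pair with methods
collapsed, because reference PPI databases are undirected. An edge is
"known" if its pair occurs in at least one reference edge list.
Localization uses an any-tag rule: a prey with at least one nuclear
compartment tag counts as nuclear, and the denominator is annotated preys
only. Bait–bait edges are edges whose prey is itself a registered bait,
excluding self-edges. The NFI partition classifies each non-NFI bait by
edge direction relative to the NFI family (to / from / both / none) and
counts either direction as a contact; per-complex coverage denominators
are the subunits detected anywhere in the dataset, since never-observed
subunits cannot be covered.

## Clustering

The bait-by-prey matrix holds average spectral counts, 0 for pairs that
did not survive filtering. Either axis can be clustered agglomeratively
(scipy linkage) with Euclidean distance or 1 − Pearson correlation;
average linkage is the default, with complete linkage exposed. The
prey–prey analysis correlates prey profiles across baits (requiring ≥ 2
baits; constant profiles are excluded and reported) and clusters on
1 − r. Flat clusters come from a user-specified k or height cut — the
number of biologically meaningful clusters is a property of each dataset,
not a constant — and are labeled A, B, C, ... in dendrogram leaf order,
which makes labels deterministic but dataset-specific. Driving baits are
ranked by how many cluster members appear in the bait's filtered
interactome, ties broken alphabetically.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) with all counts conditioned on an explicit background (for
interactome subsets, typically all preys identified in the study), and
Benjamini–Hochberg adjustment across terms. Term membership is
intersected with the background before counting; query genes outside the
background are dropped with a warning. This is a plain hypergeometric
test: tools that modify the statistic (e.g. EASE-style leave-one-out)
will give different p-values on the same counts.

## The synthetic-data generator

`SimConfig` defaults describe a scaled-down multi-bait study: 12 baits ×
150 candidate preys plus 50 contaminants, 2 biological × 2 technical
replicates per bait and method, 16 negative-control runs per method, and
a 716-experiment contaminant repository so the 358/716 and 179–358/716
frequency bands are exercised verbatim.

* **Counts** are negative binomial (mean m, size r, variance
  m + m²/r; default size 2.0) — spectral counts are overdispersed
  relative to Poisson.
* **True edges** are planted per bait–prey with probability 0.12; each
  planted edge has a latent abundance, log-normal around
  `mean_true_count` = 15 with σ = 0.8, shared across replicates and
  methods. This between-edge abundance spread is what gives replicate
  runs their correlation and the clustering heatmaps their gradient.
* **Methods differ only in capture**: BioID captures every planted edge
  (probability 1.0), AP-MS a stable subset (0.35), emulating
  transient-vs-complex detection.
* **Contaminants** each draw a detection frequency uniform on
  [0.05, 0.95] and a latent abundance around `mean_contam_count` = 10;
  they appear in bait and control runs alike with that frequency, and
  the repository table combines the simulated control detections with
  binomially drawn pseudo-experiments up to n_experiments.
* **Planted modules** ((n_preys, n_baits) blocks carved from disjoint
  pools) wire module preys to exactly the module's baits, providing
  exact ground truth for prey-correlation clustering.

What the generator does **not** emulate: peptide-level identification
(and hence shared-peptide ambiguity), bait-expression differences,
batch effects, interactions between contamination and bait identity, and
correlated contaminant structure. Passing tests therefore demonstrate
that the cascade and downstream analyses behave correctly under the
stated statistical assumptions, not that any particular real dataset
satisfies those assumptions.

## Numerical and design choices

* All tables are tab-separated UTF-8 with one header line; floats are
  written with `repr` so read↔write round trips are bit-exact.
* Gene identifiers are opaque case-sensitive strings; no symbol mapping.
* Undirected pairs are normalized to lexicographic order; normalization
  is idempotent.
* Clustering is seed-free and deterministic; scipy's linkage tie-breaks
  by merge index, so permuting input rows preserves tree topology.
* Problem sizes throughout tests and the acceptance script are the
  generator defaults above (hundreds of candidate interactions per
  seed); they are large enough for the stochastic properties checked
  (precision/recall bounds, binomial frequency agreement) while keeping
  any single test run to seconds.
* Exit codes of the CLI: 0 ok, 1 validation/format error, 2 runtime
  error.

## Known limitations

The surrogate scorer is a ranking heuristic, not a calibrated
probability; its scores should not be compared across experiments. The
repository-frequency rules assume the contaminant repository and the
study share an instrument/protocol regime. Cluster letters are not
stable across datasets or cut levels. Enrichment treats gene sets as
flat (no ontology-graph propagation).
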