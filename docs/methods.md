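# Methods

This note records the models, conventions and numerical choices behind
`coelunet`, in the order the pipeline runs.

## Fraction scheme and retention time

A SEC run is described by `FractionScheme(n_fractions, start_s, width_s)`,
default 60 fractions collected every 19 s starting at 9 min.  Retention
time uses the midpoint convention, `rt(f) = start_s + (f − 0.5)·width_s`
(1-based fractions), chosen so that the retention-time difference between
fractions `f` and `f+Δ` is exactly `Δ·width_s`; two fractions therefore
correspond to 38 s, the default reproducibility tolerance of the
differential stage.

## Synthetic complexome

The simulator is first-class code, not a test fixture.  It emulates:

* **Planted complexes.**  Disjoint member sets of 3–6 proteins (default 40
  complexes over 300 proteins).  Each complex elutes as a Gaussian bump in
  fraction index; all members share the complex's apex (plus per-protein
  jitter, SD 0.4 fractions) and peak width (drawn once per complex from
  1.5–2.5 fractions, shared so that noise-free member profiles are exactly
  proportional).  A Gaussian peak is the standard approximation for a SEC
  elution band; no shape is prescribed by the data themselves.
* **Mass-consistent elution.**  Monomer masses are drawn uniformly from
  20–120 kDa and a complex's apex is placed where its *total* mass elutes
  under a log-linear SEC calibration (log10 kDa = 3.745 − 0.0457·fraction,
  ~5 MDa at fraction 1 down to ~10 kDa at fraction 60).  Background
  proteins elute at their monomer mass.  This gives the molecular-weight
  filter a well-defined ground truth: complex members always elute at an
  apparent mass at or above their annotated monomer mass.
* **Abundance and noise.**  Base peak heights are log-uniform over three
  orders of magnitude (10^6–10^9).  Each replicate applies i.i.d.
  multiplicative log-normal noise with CV = `noise_cv` (default 0.1,
  mean-one parameterization) and completely-at-random dropout to missing
  (default 5 %), applied after noise so that missingness is a distinct
  state, never a zero.
* **Condition effects.**  A fold change multiplies all members of a
  differential complex equally in every non-baseline condition (default:
  complexes C001–C005 at 2.0), so differential recovery has an exact truth
  set.  The first configured condition is the baseline.

Companion fixtures: three overlapping complex-table dialects (each planted
complex appears in at least one), a proteome FASTA with UniProt-style
`sp|ACC|NAME` headers, and — controlled by `decoy_fraction` — decoy
complexes and contaminant members whose accessions are deliberately absent
from the FASTA, so refinement has real work to do.

What the simulator does **not** emulate: peptide-level quantification,
chromatographic drift between replicates, intensity-dependent missingness,
correlated noise across fractions, overlapping complex membership, and
proteoform heterogeneity.  Passing tests therefore demonstrate the
machinery is correct and well-calibrated under idealized conditions; they
do not certify performance numbers on real CF-MS data.

## Gold standard

Complex tables are parsed per dialect (configurable id/member columns,
`;` or `,` delimiters), members trimmed and deduplicated.  Refinement drops
members absent from the proteome FASTA (isoform suffixes such as `-2` are
stripped before matching, configurable) and then drops records left with
fewer than two members; it is idempotent.  Pair expansion takes the union
of all unordered within-complex pairs across sources; single-member
records are tracked as monomeric and excluded from the modeling positive
set, because a self-pair has no pairwise elution features.

Labels over the matrix proteins: *positive* if the pair is a gold-standard
pair; *negative* if both proteins occur anywhere in the refined gold
standard but the pair is not positive (the convention of co-elution
interactomics tooling); *unknown* if either protein is absent from the
gold standard.  The three labels always partition all N(N−1)/2 pairs.

## Peaks and QC

Peak calling 3-point-smooths the trace (missing → 0; edge-replication
padding, so a monotone trace keeps its apex at the boundary) and takes
local maxima with prominence ≥ 10 % of the smoothed global maximum.  The
peak region walks from the apex to the nearest local minimum or the first
fraction below 10 % of the apex value; the area is the trapezoidal
integral of the raw trace over that region in intensity × seconds.  Both
thresholds (`min_prominence_frac`, `boundary_frac`) are exposed.

Replicate QC reports the Jaccard coefficient of identified-protein sets,
Spearman correlation of shared summed-trace abundances, and the
per-protein CV (sd/mean × 100 %, ddof 1) across replicates.

Trace normalization supports both readings of "divided by total
intensity": `per_fraction_total` (each cell over its fraction-column
total) and `per_protein_total` (each cell over its row total).  Both are
kept because the two descriptions in circulation are ambiguous between
them; `per_protein_total` is the default for trace display.

## Co-elution features

For a pair of traces over the same scheme:

* `pearson_raw` — Pearson r over the jointly observed fractions
  (`n_valid` of them).  Fewer than 3 joint fractions or zero variance on
  the joint support gives 0 with a flag, never NaN.
* `pearson_smoothed` — same, after a centered moving average with window 3
  (the smallest non-trivial window; shrinking at the edges, missing → 0).
* `euclidean` — L2 distance after dividing each trace by its own maximum
  (missing → 0).  Max-normalization keeps this feature scale-free, so the
  composite score's −0.01 weight acts as a mild tiebreaker rather than
  dominating on raw intensity scales; raw-scale distance is available by
  normalizing upstream.
* `co_peak` — peaks are called on each trace, apexes greedily matched by
  increasing distance within ±1 fraction (configurable), and the score is
  matches / max(#peaks); 0 if either trace has no peak.  Symmetric.
* `wcc` — triangularly weighted cross-correlation over lags |l| ≤ w
  (default w = 1), normalized by the same weighted autocorrelations; the
  triangular kernel is positive semidefinite, so the score stays in
  [−1, 1]; all-zero signals give 0.

The co-peak and WCC formulations are declared conventions of this package,
validated by property tests (symmetry, scale invariance, brute-force
equivalence) rather than against any external reference implementation.

Feature tables for many pairs are computed on across-replicate mean traces
of one condition (positions missing in all replicates stay missing), with
per-protein traces and peak calls cached.

## Two-phase training-set construction

Phase one keeps every positive and a seeded uniform sample of 5× as many
negatives (all of them, with a warning, if fewer exist).  A 500-tree
random forest on the five features produces *out-of-fold* scores via
5-fold stratified CV — selection scores are never in-sample, to avoid
leaking the pair into its own filter.  Positives scoring strictly > 0.5
proceed to augmentation.

Phase two generates 200 candidate variants per selected pair.  Each
variant multiplies every observed value independently by a uniform draw on
[0.9, 1.1] (per-value rather than per-profile, for diversity) and then
visits every originally missing position, either leaving it or swapping it
with an adjacent fraction (uniform direction; inward at the edges) —
swapping conserves the observed values.  Variants are ranked by

    composite = n_valid × 0.5 + |pearson_raw| × 30 − euclidean × 0.01

with ties broken by candidate index, and the top 40 plus bottom 10 are
retained (50 per pair).  Keeping the low-scoring tail follows the printed
procedure of the workflow this package implements; whether those variants
act as hard positives or noise is an open question, so the head/tail split
is recorded per variant.  Only positives are ever augmented.

## Classifier and evaluation

The balanced dataset holds originals + variants (label 1) and negatives
sampled without replacement to match exactly (topping up from the full
negative label set if the staged pool is exhausted).  The group key of a
row is the lexicographically smaller accession of its pair: grouping "by
protein" is ill-posed for pairs on a connected interaction graph (a fully
protein-disjoint three-way split is generally impossible), and anchoring
on one protein guarantees no anchor appears in two partitions while
keeping every variant in its parent pair's partition.  GroupShuffleSplit
allocates groups at 80/10/10.

Hyperparameters are tuned by exhaustive grid search over
max_depth {4, 6, 8} × learning_rate {0.01, 0.05, 0.1} ×
subsample {0.6, 0.8, 1.0} (concrete points chosen inside the printed
ranges), each scored by 3-fold label-stratified CV AUPRC on the training
partition.  The winner is retrained with up to 500 rounds and early
stopping after 20 rounds without AUPRC improvement on the validation
partition; `scale_pos_weight` is the training negative:positive ratio.

Evaluation: AUROC (trapezoidal) and AUPRC (step) from scikit-learn;
*strict precision* at a threshold (default 0.95) counts unknowns among the
false positives, TP/(TP+FP); the *weighted precision curve* sorts
predictions by probability (ties by id) and scores rank k as the mean
weight of the top k, with weights 1 / 0 / predicted-probability for
positive / negative / unknown.  With no unknowns it reduces exactly to
cumulative strict precision, and it dominates strict precision at every
rank.  External data are evaluated with features + prediction only — no
augmentation — since augmentation exists solely to enrich training
positives.

## Differential analysis

Pair intensity in one replicate is the sum of the two proteins'
dominant-peak areas.  Before peak integration the chromatogram is
*reconstructed*: interior missing fractions are linearly interpolated
(leading/trailing gaps stay missing).  Without reconstruction a single
dropped fraction near an apex splits the peak and truncates the
integration region, inflating replicate variance several-fold.

Significance uses a nested Gaussian means model on log2 pair intensities:
null = common mean, alternative = per-condition means with shared
variance.  The reported statistic is Λ = n·ln(RSS₀/RSS₁) with a relative
variance floor of 1e−6 × mean² guarding zero-variance replicates; the
p-value is taken from the exact finite-sample reference of the equivalent
F statistic, F(1, n−2).  At 3 + 3 replicates the χ²(1) asymptote rejects a
true null ~13 % of the time at α = 0.05, whereas the F reference is exact —
simulated null p-values are uniform (KS < 0.05 at 10 000 replicates) and
the type-I error sits at the nominal level.  Benjamini–Hochberg correction
is applied across pairs.

A pair is called differential iff all of:

* retention-time reproducibility: for each protein, in each condition, the
  maximum pairwise apex-RT difference across replicates ≤ 38 s (two
  fractions at 19 s); the per-protein maximum over replicate pairs is the
  aggregation, boundary inclusive;
* molecular weight: apparent mass at the (median) apex under the fitted
  log-linear calibration ≥ the annotated UniProt-style monomer mass for
  both proteins (boundary inclusive — failing only strictly below); pairs
  with a missing annotation are excluded with a reason;
* q ≤ 0.05 and a two-sided fold-change rule, FC > 1.5 or FC < 1/1.5
  (equivalently |log2 FC| > log2 1.5), on the mean-based fold change.  The
  median of replicate-ratio fold changes is reported alongside but does
  not gate the call.

The filters commute: applying them in any order yields the same call set.

Called pairs are clustered on the Euclidean distance of their z-scored
intensity profiles with average linkage and the dendrogram cut at a fixed
height (default 50, appropriate for z-scored rows; the height is in the
units of the clustered matrix and must be rescaled if the input is not
row-scaled).  By default every branch below the cut is a module — so a cut
near 0 yields one module per row — and `pool_singletons=True` additionally
pools rows that never merge below the cut into one extra module X + 1.

## Problem sizes and determinism

The bundled end-to-end run uses 300 proteins, 40 complexes, two conditions
× three replicates, ~2 100 staged pairs, ~250 augmented positives (50
variants each) and a ~25 000-row balanced dataset — sizes chosen so the
whole pipeline completes in about a minute on one core while keeping every
stage's statistics meaningful.  All randomness flows from explicit integer
seeds through `numpy.random.default_rng` / `SeedSequence.spawn`; identical
seeds give bit-identical serialized outputs.

## Known limitations

* Features are computed on replicate-averaged traces of one condition;
  per-replicate feature instances are not modeled.
* The negative-to-positive universe of a small simulation can be exhausted
  by 50-fold augmentation (positives × 51 can exceed the number of
  negative-labeled pairs); the assembler then raises with exact counts
  rather than silently unbalancing.
* The LRT assumes log-normal replicate intensities with shared
  within-group variance; heavy-tailed deviations are not modeled.
* The weighted precision curve treats predicted probabilities of unknowns
  as calibrated; no recalibration is performed.
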