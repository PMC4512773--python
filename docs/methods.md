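# Methods

## Model and procedure

`metaboot` treats biomarker discovery as stability selection over a
minimal-redundancy feature ranking.  The data model is a feature × sample
abundance matrix with a two-class sample design, optionally refined into
subclasses (batches, time points, sub-phenotypes) that act as strata.

**Discretization.**  Mutual information on continuous abundances is
estimator-sensitive; the pipeline instead codes each feature into three
levels around its own center: +1 above μ + σ/2, −1 below μ − σ/2, 0
between.  Thresholding is strict, so a value exactly on a threshold codes
to 0, and a constant feature (σ = 0) codes to all zeros.  σ is the sample
standard deviation (n − 1 denominator) by default; the `ddof` argument
exposes the population convention.  The coding is invariant under
positive affine rescaling of a feature, which makes selection insensitive
to per-feature units.

**MID objective.**  Relevance is the plug-in mutual information I(x; c)
in bits between a feature's codes and the class label (never the
subclass); redundancy is the mean pairwise MI against the already
selected set; the greedy step maximizes their difference.  No
small-sample bias correction is applied — the plug-in estimator on
3-level codes is the classical choice for this selection scheme, and the
bias is common to all candidates at a fixed step.  Objectives within
1e-10 of the step maximum are treated as mathematical ties (identical MI
sums accumulated in different orders differ by an ulp) and broken by
higher relevance, then lower input index, so runs are bit-reproducible
across platforms.  Pairwise MI against each newly selected feature is
computed once for all candidates per step (vectorized over features), so
a k-feature selection costs k vectorized MI passes.

**Bootstrap stage and occurrence ranking.**  Each of the B replicates
draws, within every stratum, as many samples as the stratum originally
had (with replacement), preserving the design exactly.  Each replicate is
treated as a fresh dataset: the candidate features are re-discretized on
the resampled columns before mRMR re-selects M′ of them.  This matches
the view of the bootstrap as "run the same selection tool on a new
dataset" and measurably improves the recovery of true markers over
reusing the full-table codes; the cheaper reuse variant is kept behind
`rediscretize_per_bootstrap=False`.  Final ranking is by occurrence
count across the B lists; ties break by lower mean within-bootstrap rank,
then lower first-stage rank (the published procedure does not specify tie
handling, so a fully deterministic rule was fixed).  Degenerate
replicates (e.g. a class collapsing to near-constant codes) are kept, not
resampled: relevance is then ~0 for all candidates and the tie-break
produces a deterministic, seed-reproducible list.

**Randomness.**  One root seed feeds a `numpy` `SeedSequence`; bootstrap
replicate b uses spawned child b.  Streams are therefore nested: raising
B appends new replicates without changing earlier ones, which makes the
unique-features-vs-B saturation curve non-decreasing by construction and
supports the elbow procedure for choosing B.

## Parameters

| parameter | default | meaning |
|---|---|---|
| M | 50 | first-stage candidate count; choose at the saturation point of distinct marker groups vs M |
| B | 40 | bootstrap replicates; choose where the distinct-feature curve plateaus |
| M′ | 10 | final panel size (must be < M); 10 matches the benchmark designs' 10 marker groups |
| zero_fraction | 0.8 | sparsity filter; a feature with ≥ 80% zeros is dropped (boundary inclusive) |
| ddof | 1 | σ convention for discretization |

For the 100-feature robustness protocol the first stage uses M = 200
(the published experiments do not state M for that setting; 2× headroom
over M′ = 100 keeps the 900 background features screened while leaving
room for weak positives).

## Synthetic benchmarks

The generators emulate abundance tables whose per-taxon distributions are
normal, gamma, or a class-dependent mixture — the three regimes observed
in real 16S genus-level profiles.  All three designs share the ground
truth layout: 10 positive groups × 10 redundant features + 900 negatives.

* **S1** — 120 samples (2 classes × 3 subclasses × 20).  Positive
  features draw a per-(feature, subclass) mean from {11, 12, 13, 14} in
  one class and {17, 18, 19, 20} in the other (groups 6–10 reversed);
  negatives all have mean 15; every feature shares one sd (default 1.0,
  exposed as the difficulty dial).  Drawn means are recorded in the
  dataset provenance.  An option draws one mean per (feature, class)
  instead; the per-subclass draw is the default reading of the design.
* **S2** — 100 samples (2 × 2 × 25).  Groups 1–5 gamma in both classes
  with class-separated shapes; groups 6–10 gamma in class 1 and normal in
  class 2 with moments matched to the corresponding gamma archetype, so
  their signal is a shape difference at equal location; negatives
  normal(0.14, 0.06).  One printed parameter in the source design is
  internally inconsistent: group 10's class-2 sd is listed as 0.06, which
  contradicts the stated construction (match the gamma archetype's
  moments; that sd is 0.0049) and duplicates the neighbouring
  background-sd column.  Taken literally it turns group 10 into a
  variance outlier that absorbs every method's entire selection (measured
  non-redundancy collapses to the 10% floor, inconsistent with every
  published summary of this design).  The generator therefore uses 0.005,
  the value the construction rule implies.
* **S3** — 120 samples (2 × 3 × 20), all gamma; positive shapes (and for
  most groups rates) differ between classes; three negative blocks of
  300 features are subclass-invariant.  Gamma is parameterized by
  (shape, rate), mean = shape/rate; numpy's scale is 1/rate.

Normal blocks are left untruncated (occasional small negative values);
benchmark matrices carry the "ready for selection" flag and are never
renormalized, since the block distributions are defined on the generated
scale.

**What the generators do not emulate:** compositional coupling (features
are independent given the design), sequencing-depth variation and count
noise, the long tail of rare taxa, and feature-feature correlation
beyond group membership.  Passing benchmarks here demonstrates correct
selection mechanics and robustness to distribution shape, not
performance on real sequencing data.

**Detection ceilings.**  At the printed parameters, S3's positive group 4
is essentially undetectable by rank-based comparison (its class-2 rate
change compensates the shape change, leaving the distributions almost
exchangeable in location; large-sample AUC ≈ 0.47) and group 8 is
marginal (AUC ≈ 0.59).  At 60 + 60 samples this caps the expected
rank-sum recovery in a 100-feature panel at roughly 66–70 positives, and
mRMR-based selection shows a similar ceiling; published figures in the
low 80s for this design are not reachable from the printed parameter
grid.  The acceptance checks report the measured values unchanged.

## Evaluation

* **Non-redundancy / redundancy** (percent of the panel): a selected
  positive is redundant when its group already has an earlier selected
  representative; negatives never count as redundant.
* **Error rate**: percent of the panel that is background (negative).
* **Rank-sum comparator**: two-sided Wilcoxon rank-sum per feature
  between classes, smallest p first; scipy's exact null for tiny
  tie-free groups, otherwise the tie- and continuity-corrected normal
  approximation.
* **SVM accuracy**: RBF kernel, per-fold min-max scaling to [−1, 1]
  fitted on training data, (C, γ) grid-searched by inner 5-fold CV over
  log2 C ∈ {−5, −3, …, 15} and log2 γ ∈ {−15, −13, …, 3}, outer
  stratified k-fold (6-fold for the 60 + 60 design).
* **Exact permutation test**: difference of group means, full
  enumeration up to a combined size of 20 (C(14,7) = 3432 for 7 vs 7),
  Monte-Carlo with 20,000 draws beyond that; two-sided, symmetric in
  group order, shift-invariant.
* Replicate aggregation reports mean ± sample sd across seeds.

## Problem sizes and numerical choices

The replicated benchmark computations (tests and the acceptance script)
use 10–20 independently seeded replicates of the full-size designs
(1,000 features, 100–120 samples); a full acceptance run is ~70 s on one
CPU.  Comparison tolerances: MI oracle agreement to 1e-12; greedy-step
tie tolerance 1e-10; normalization column sums to 1e-9.  Degenerate
inputs fail fast with typed errors (zero-total samples, single-class
labels, empty strata, M ≤ M′, k beyond the feature count).

## Known limitations

Two-class designs only (one-vs-all multi-class selection is out of
scope); no BIOM/HDF5 input; no compositional (multinomial) noise model
in the generators; plug-in MI without bias correction is fine for
ranking at fixed n but its absolute values are biased upward for small
samples.
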