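# metaboot

Non-redundant taxonomic biomarker discovery for microbial communities.

Given a taxa-by-samples relative-abundance table (16S profiles summarized
at, say, genus level) and a two-class sample design, `metaboot` finds a
small panel of taxa that discriminates the classes while avoiding the two
failure modes of naive differential-abundance ranking: **redundancy**
(picking ten near-identical strains that all carry the same signal) and
**instability** (panels that change wholesale when a few samples are
resampled).  It is aimed at microbiome researchers benchmarking biomarker
selection methods and at anyone who needs a reproducible, seed-stable
marker panel from a compositional abundance table.

## The method

1. **Preprocess.**  Counts are converted to relative abundances (each
   sample column divided by its total), taxa that are zero in ≥ 80% of
   samples are dropped, and each feature *x* is discretized by its own
   mean μ and standard deviation σ into three levels:
   +1 if *x* > μ + σ/2, −1 if *x* < μ − σ/2, else 0.
2. **Screen (mRMR, MID).**  Greedy minimal-Redundancy-Maximal-Relevance
   selection on the discretized matrix keeps the *M* best candidates.  At
   step *t* the objective for an unselected feature *x_j* is

   I(x_j; c) − (1/|S|) Σ_{x_i ∈ S} I(x_j; x_i)

   with *c* the class label, *S* the selected set, and I the plug-in
   mutual information (bits) over the empirical joint histogram.
3. **Bootstrap.**  *B* stratified bootstrap replicates resample the
   samples with replacement *within each subclass*, so every replicate
   keeps the original design; mRMR re-selects the top *M′* candidates on
   each replicate (re-discretized per replicate).
4. **Rank by occurrence.**  Candidates are ranked by how many of the *B*
   bootstrap lists contain them; the *M′* most frequent are the final
   biomarkers.  Defaults: M = 50, B = 40, M′ = 10.

The package also ships the three synthetic benchmark generators used to
validate the method — S1 (normal blocks), S2 (gamma/normal mixture),
S3 (all gamma), each 1,000 features with 10 redundant positive-marker
groups of 10 plus 900 negatives and full ground truth — together with
the evaluation harness: non-redundancy/error rates, positive-marker
counts, a rank-sum comparator, cross-validated RBF-SVM accuracy, and an
exact permutation test for tiny group comparisons.

## Worked example

```sh
python examples/02_select_biomarkers.py
```

```
final biomarkers (occurrence / 40 bootstraps):
  pos_g02_f02     33   group=pos_g02
  pos_g02_f01     32   group=pos_g02
  pos_g02_f05     29   group=pos_g02
  pos_g02_f04     25   group=pos_g02
  pos_g03_f06     24   group=pos_g03
  pos_g04_f06     22   group=pos_g04
  pos_g04_f01     19   group=pos_g04
  pos_g02_f08     18   group=pos_g02
  pos_g04_f02     16   group=pos_g04
  pos_g02_f09     13   group=pos_g02

non-redundancy rate: 30%  (unique marker groups among the 10 picks)
error rate: 0%  (background taxa selected)
```

Each selected feature is shown with the number of bootstrap replicates
(out of 40) whose mRMR top-10 contained it — its stability — and the
ground-truth group it belongs to.  Here all ten picks are true positive
markers (error 0%) spanning three distinct marker groups (non-redundancy
30% for this seed); a method with no redundancy control typically
returns ten copies of a single group (10%).  The other examples cover
simulation (`01`), replicated method comparison (`03`), choosing M and B
by saturation (`04`), SVM panel evaluation (`05`) and the exact
permutation test (`06`).

The same pipeline is available from the shell:

```sh
metaboot simulate --design s2 --seed 7 --out s2_demo
metaboot select s2_demo/abundance.tsv s2_demo/metadata.tsv \
    --method metaboot -M 50 -B 40 --m-prime 10 --no-preprocess --out panel.tsv
metaboot evaluate panel.tsv s2_demo/ground_truth.tsv
```

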