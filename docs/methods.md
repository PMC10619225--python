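# Methods

## Overview

`hascad` estimates the fractions of 15 immune cell types in bulk RNA-seq
from an ensemble of feed-forward networks trained on pseudo-bulk samples
simulated from a batch-corrected single-cell reference. This note records
the model, its assumptions, the defaults and why, and what the synthetic
study can and cannot show.

## Reference construction

**Normalization.** Single-cell counts are transformed to
log2(count / cell_total x 1e4 + 1) (log-CP10K). Bulk queries may instead
use log2(TPM+1); the projection step absorbs the resulting per-gene shift
as a batch-like offset.

**Variable genes.** Genes are ranked by standardized variance about a
mean-variance trend: a degree-2 polynomial of log10(variance) on
log10(mean) fitted across expressed genes, with per-gene values
standardized by the trend SD and clipped at sqrt(n_cells) before the
variance is recomputed. The default keeps 512 genes at desk scale (the
analogous full-scale selection keeps a few thousand of ~20k). Per-gene
mean and observed SD of the retained genes are stored; standardization
clips z-scores at +/-10.

**Embedding.** The standardized genes x cells matrix is factorized by SVD;
`U` holds the top-d loadings and `Z = sigma V^T` the cell coordinates.
d = 20 by default (common practice for PBMC-scale references; the method
is insensitive between 15 and 30 on the synthetic study). Component signs
are fixed so the largest-magnitude loading is positive, making repeated
runs bit-identical.

**Batch correction.** The correction alternates two steps, following the
Harmony recipe:

1. *Diversity-penalized soft k-means* on the cosine sphere. Assignments
   are `R ∝ exp(-d²/sigma) * ((E+1)/(O+1))^theta` where `O` is the
   observed cluster-by-batch co-occurrence and `E` its expectation under
   the global batch proportions; cells are updated in random 5% blocks
   with `O`/`E` kept current. Defaults: K = min(100, cells/30), theta = 2,
   sigma = 0.1, max 10 outer iterations, relative objective tolerance 1e-4.
2. *Mixture-of-experts ridge correction.* Per cluster, a weighted ridge
   regression on [intercept; batch one-hots] is solved against the
   embedding and the batch terms are subtracted, weighted by membership.

Two numerical choices depart from a naive transcription of that recipe
and are deliberate. First, per-batch grand means are aligned before
clustering (the K = 1 limit of the correction). Second, they are
re-aligned after every correction pass: because the diversity penalty
makes soft weights batch-dependent, the summed per-cluster corrections
can otherwise reintroduce a net global batch offset (we observed ~10% of
a pure translation reinjected). With the constraint, a pure translation
between batches is removed exactly, which is also what the test oracle
checks. The ridge penalty defaults to 1e-3; with the grand-mean
constraint in place the near-collinearity of [intercept; batch one-hots]
is harmless.

**Reconstruction.** `U @ Z'` is mapped back through the inverse
standardization (x SD, + mean) and clipped at zero. The corrected
expression is on the log-CP10K scale; training and inference only require
a consistent representation, so no count back-transform is attempted.

**Query projection.** Queries are aligned to the reference genes by id
(missing genes imputed at the reference mean, i.e. zero after
standardization; at least 50% overlap required), standardized with the
*reference* statistics, and embedded as `Z_q = U^T x`. Samples are softly
assigned to the reference clusters and the membership-weighted offset
from the reference cluster means is removed with ridge shrinkage
(query_ridge = 1.0, deliberately stronger than the reference ridge so a
handful of query samples is not collapsed onto the reference centroids).
Bulk samples are treated exactly like single cells.

## Pseudo-bulk simulation

A sample's composition is drawn uniformly per type and normalized
("dense"), optionally after zeroing a random subset of types ("sparse"),
or set to a one-hot vector ("pure"). Cell counts per type follow
largest-remainder rounding of fraction x cells_per_sample (ties broken in
vocabulary order); cells are drawn with replacement, within-type pools
sorted by cell id so the draw is invariant to pool ordering. The sample
profile is the per-gene mean of the drawn cells. cells_per_sample
defaults to 500 — the count is not critical, it trades sampling noise
against runtime. Training sets default to 8,000 samples.

Mixing operates on the corrected log-expression by default; a flag (the
`normalized_expression` pool) mixes raw log-CP10K for the uncorrected
baseline, keeping the two pipelines on the same genes and scale.

## The ensemble model

Three parallel MLPs with hidden sizes 1024/512/256, 512/256/128 and
256/128/64 (first layers as published; deeper layers geometrically halved
within the allowed [32, 1024] range), ReLU activations, softmax output
over the 15 types. Inputs are standardized per gene with training-set
statistics stored in the model. The prediction is the arithmetic mean of
the three softmax outputs — a convex combination, so it stays on the
simplex.

The loss per sample is `MSE + (1 - r)`, with `r` the Pearson correlation
across the 15 types; `r := 0` when either vector is constant across types
(so a constant truth costs the full PCC unit). The correlation is
per-sample rather than minibatch-flattened, matching the per-sample
evaluation metrics. Optimization is Adam (lr 1e-4, beta 0.9/0.999, batch
64, shuffled epochs); early stopping monitors validation loss with
patience 20 and restores the best weights; max_epochs defaults to 500.
Networks, backpropagation and Adam are implemented directly on numpy
(float32); gradients are verified against central differences in the test
suite. Inter-layer dropout is available but off by default — on the
noise-free synthetic study it only slows convergence.

Softmax is applied per module before averaging (each module has its own
output layer).

## Synthetic study design

The generator emulates the ingredients the correction is meant to handle:

- each type up-regulates a disjoint block of n_genes/30 marker genes by
  `program_effect_size` = 4 on the log2 scale over a shared log-normal
  baseline (disjoint blocks make ground truth unambiguous; the magnitude
  reflects that canonical PBMC markers are near on/off, and yields
  cleanly separable types in the absence of batch effects);
- each batch multiplies every gene by its own log-normal factor
  (SD = 1.0 on the natural-log scale), constant within the batch — the
  linear mechanism a Harmony-style correction can provably remove;
- per-cell library sizes are log-uniform in [1000, 5000]; counts are
  Poisson (negative-binomial optional, dispersion 2) followed by
  Bernoulli dropout at rate 0.3.

Defaults (3 batches, 30-80 cells per type per batch, 1,000-2,000 genes)
mirror the order of magnitude of public multi-chemistry PBMC references
scaled down. At these settings, k-means on the raw embedding agrees with
true types at ARI ~0.13 while the corrected embedding reaches ~0.98, and
the batch-mixing entropy rises from ~0 to near its theoretical maximum —
the qualitative picture the correction is designed to produce.

**What this does not show.** The generator has no doublets, ambient RNA,
cell-cycle structure, chemistry-specific read artifacts, or biologically
correlated batch-by-type interactions; its batch effect is exactly the
linear mechanism the correction targets. Passing tests therefore
demonstrate internal correctness and the benefit of correction under
linear batch confounding, not performance on real PBMC data.

## Evaluation protocols

- Per-sample PCC and MSE across the 15 types; zero variance gives PCC 0
  with a warning.
- Subtype aggregation: parent fraction = sum of child fractions; mass not
  covered by the mapping is reported as "other". The pure-type benchmark
  maps bnaive+bmem to B cells, cd4mem+cd4naive+treg to CD4 T cells,
  pDC+aDC to dendritic cells and mono14+mono16 to monocytes; major-type
  calls take the argmax over parents (including "other", so a call can
  fail by placing mass outside the four classes), with ties broken by
  order.
- Bland-Altman: per-type mean and SD of (prediction - truth) plus the
  pooled SD.
- 10-fold CV splits at the pseudo-bulk sample level (seeded disjoint
  folds; 10% of each training split carved out for early stopping).
- Leave-one-dataset-out holds out each batch in turn: the reference and
  training simulations use the remaining batches; test pseudo-bulk is
  simulated from the held-out batch after projection into the reference
  (corrected pipeline) or from its raw log-CP10K profile (baseline).

## Desk-scale problem sizes

The acceptance study uses 3 batches x 15 types x 50 cells, 1,000 genes
(512 selected), 8,000 pseudo-bulk samples of 500 cells, 10-fold CV with
max_epochs 40 (the networks converge well within that on this data; the
published full-scale analogue converges in ~80 epochs). The in-suite
version of the same study is smaller (600 genes, 40 cells/type/batch,
2,500 samples of 300 cells, max_epochs 25) so the whole test suite stays
fast; both use identical thresholds.

## Known limitations

- The correction removes linear, cluster-wise batch offsets only;
  non-linear or type-specific-in-a-nonlinear-way batch effects are out of
  scope.
- Query projection with very few samples shrinks toward the reference
  (by design, via query_ridge); single-sample projections are
  conservative.
- The 15-type vocabulary is fixed; retraining is required for other
  panels.
- Mixing averages log-scale expression directly rather than re-summing
  counts; this matches the training representation but is not a physical
  read-level simulation.
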