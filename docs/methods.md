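# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of the package. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## Backbone

A four-stage recurrent convolutional classifier in the CORnet-S family.
Stage V1 is feed-forward: 7×7 convolution (stride 2), 3×3 max-pool
(stride 2), 3×3 convolution, each followed by ReLU. Stages V2, V4 and IT
are weight-shared bottleneck blocks (1×1 → 3×3 → 1×1 convolutions with a
residual connection) traversed 2, 4 and 2 times respectively; the 3×3
convolution strides by 2 only on the first pass, with a strided 1×1
projection on the skip path. A global-average-pooled linear decoder
produces category logits. Instrumented pass counters verify the recurrence
schedule on every forward call.

Differences from the full-scale architecture, all deliberate desk-scale
choices:

- **No batch normalisation.** Small plain conv+ReLU stacks train stably at
  this scale and keep the autodiff graph simple; dropping BN also removes
  train/eval statistics as a source of non-determinism.
- **Small channel widths** (library default 16/32/64/128; the experiments
  use 8/16/16/32). Large-scale image pre-training is out of scope; instead
  a documented `pretrain_classifier` step trains the backbone on the
  synthetic categories to provide the image-trained starting point.
- **Weight initialisation** is fan-in-scaled Gaussian under the run seed.

For representational analyses, "layer features" are the final recurrent
pass of each stage, post-ReLU, pre-pool, flattened. This is one of several
defensible conventions; it is fixed here because the final pass is the
stage's output by definition of the recurrent block.

## Autodiff engine

No deep-learning framework is assumed: `realign.minidiff` is a ~400-line
reverse-mode autodiff on float64 numpy arrays providing exactly the
primitives the model needs (broadcasting arithmetic, matmul, im2col
convolution, max/average pooling, reductions, concat, log-softmax, a fused
cross-entropy, Adam). Gradient correctness is established by
central-difference checks in `tests/test_minidiff.py` (agreement to ~1e-9)
rather than assumed; the composite training losses are gradient-checked
end to end in `tests/test_alignment.py` during development of the suite.

## Alignment objective

`L_A = L_C + β·L_G`, with `L_C` the mean categorical cross-entropy against
teacher labels (the argmax predictions of the frozen image-pretrained
backbone — a stand-in for labels the dataset lacks) and

```
L_G = MSE + [1 − mean_i ρ(S_i, Ŝ_i)] + mean_{i≠j} ρ(S_i, Ŝ_j)
```

Numerical conventions, each flagged because the high-level description
leaves them open:

- **MSE is averaged over samples *and* features**, so β is comparable
  across response dimensionalities. A feature-summed variant would rescale
  β by `fmri_dim`.
- **ρ is Spearman in evaluation mode** (average ranks, exact, matches a
  brute-force pairwise loop to 1e-10). **Training mode uses a
  differentiable surrogate**: Pearson correlation of z-scored signals by
  default, optionally a soft-rank Spearman (pairwise sigmoids with
  temperature, default 0.1). Hard ranks have zero gradient almost
  everywhere; the surrogate preserves the contrastive geometry, and the
  logged/evaluated quantities are always the exact form.
- **Constant signal rows** (zero rank variance) have their correlations
  defined as 0, with a warning.
- Batches of size < 2 are dropped (the contrastive term is undefined);
  a batch of N touches N positive + N(N−1) negative pairs (256 at N=16).
- With β=0 (the Control) the generation loss is computed for logging only
  and contributes no gradient; the test suite verifies the generation head
  stays exactly at initialisation.

Defaults mirror the fine-tuning regime the framework comes from
(`train_alignment`: lr 2e-5, 5 epochs, batch 16, β 40, Adam). The
scaled-down experiments override the learning rate (below).

## Voxel preprocessing

Repeated presentations are averaged, the stimulus × voxel matrix is
PCA-reduced (transform fit on the training split only, reusable on
held-out data), default 1,024 components at full scale and 128 in the
desk-scale experiments. An optional per-feature z-scoring of the reduced
features (training statistics) exists but is **off by default in the
experiments**: whitening equalises the variance of all retained
components, which amplifies the trailing, noise-dominated PCs and degrades
the training targets. Keeping the PCA variance spectrum leaves the MSE and
correlation terms dominated by signal-bearing components.

## Synthetic teacher cortex

The generator stands in for a human brain so the pipeline is testable with
known ground truth. It emulates the *structure* of visual neuroimaging
experiments — 1,200 training images (150 categories × 8) with 5 repeats,
test sets of ~50 images, five ROIs (V1–V4, LOC), 17-channel × 20-timepoint
epoch data with 80 repeats — not their biophysics.

- **Stimuli** are parametric coloured geometric shapes on textured
  backgrounds (32 px default). Category determines shape family, hue,
  size and stripe texture; position, rotation and background are instance
  jitter. Categories are therefore classifiable but not trivially so.
- **The teacher** is the same backbone architecture at an independent
  seed, *trained on the category task* (20 epochs) and then frozen. A
  random untrained teacher is representationally undifferentiated across
  stages — its stage geometries are dominated by shared low-level
  structure — so there would be no hierarchy to recover; training
  concentrates category structure in the late stages, as in biological
  visual cortex.
- **ROI readouts**: stage activations are average-pooled to a 4×4 grid,
  z-scored per feature across stimuli, and projected through fixed random
  Gaussian maps (scaled for ~unit voxel variance) — V1←stage 1,
  V2←stage 2, V4←stage 3, LOC←stage 4, V3←mean of stages 2 and 3. The
  mapping mirrors the hierarchy assumption without claiming a true
  layer-region correspondence.
- **Repeat noise** is iid Gaussian per repeat and feature, SD 0.5 relative
  to unit signal SD for voxels. Real measurement noise levels and repeat
  reliabilities are unknown for the emulated datasets; these defaults are
  a plausible regime, not a calibration.
- **Epoch data** mix the four stages' channel projections with a linear
  latency ramp from an early-stage-dominated profile (0.70/0.20/0.07/0.03)
  to its reverse, so early timepoints carry early-stage geometry and late
  timepoints late-stage geometry. EEG-style noise defaults to SD 4.0:
  single-trial electrophysiology is noise-dominated, and this scale puts
  16-trial pseudo-trial decoding in the mid-accuracy range instead of at
  ceiling (where RDMs would degenerate to a constant).
- **Object-dimension weights** are non-negative per-stimulus tables
  (log-normal), with dimension 0 driven by category identity so that one
  dimension has recoverable block structure.

What passing tests on this generator do *not* show: robustness to
hemodynamics, preprocessing artefacts, inter-subject variability, or any
property of real fMRI/EEG noise; the teacher shares the student's
architecture family, which makes alignment easier than across genuinely
different systems.

## RSA

- Correlation-distance RDMs: `1 − Pearson` between activation rows;
  constant rows get distance 1 (ρ defined 0), with a warning.
- Decoding RDMs: per condition pair, a Fisher linear discriminant with
  shrinkage-regularised pooled covariance (shrinkage 0.2 toward the scaled
  identity), fit on pseudo-trials (shuffled repeats averaged in groups of
  ~16), stratified k-fold (default 4; reduced with a warning when
  pseudo-trials are scarce). The classifier, fold scheme and pseudo-trial
  size are field-standard defaults, chosen here because the method
  description leaves them open; all are seedable parameters. The
  implementation is vectorised over all pairs (batched d×d solves).
- RDM comparison: Spearman over the vectorised upper triangle, diagonal
  excluded (the diagonal is constant and would bias rank correlation).
  Stimulus-id mismatches are an error — no silent reordering.
- Region summaries take the maximum similarity over model layers
  (no fixed layer-region correspondence); improvement ratios
  `(aligned − baseline)/baseline` are flagged undefined when the baseline
  rho is ≤ 0 rather than reported as an unstable number.

## Partial-correlation variance partitioning

Partial Spearman = partial Pearson on rank-transformed vectorised RDMs
(average ranks for ties). The primary estimator regresses the target and
each feature vector on the remaining features (with intercept) by least
squares and correlates the residuals; rank-deficient covariate blocks fall
back to a tiny ridge penalty (1e-8) and are flagged per dimension. The
closed form from the inverse correlation matrix serves as the independent
test oracle (agreement to 1e-8 on random instances), and `pingouin`'s
partial correlation provides a third, library-independent cross-check in
the tests. Whether to rank before partialling is a genuine convention
choice; ranks-first is used throughout and documented here.

## The teacher-recovery experiment

The headline check (`realign.experiments`): per seed, simulate a teacher
cortex (200 training / 50 test images, 10 categories, 5 repeats, 64 voxels
per ROI, PCA to 128), pretrain a student backbone on the category task
(8 epochs), then train an aligned model (β = 40) and a seed-matched β = 0
Control for 5 epochs each, batch 16, Adam at lr 3e-3 — the rate for small
networks trained nearly from scratch; the 2e-5 default belongs to
fine-tuning a large pre-trained model and barely moves these weights in
5 epochs. The verdict per seed compares the ROI-mean of max-over-layers
Spearman similarity to held-out, repeat-averaged teacher ROI RDMs.

Hierarchy recovery is assessed with the teacher's *own* stage features as
the probe: does the layer × region analysis assign ROI V1 an earlier
best-matching stage than LOC? This tests that the simulation embeds a
recoverable hierarchy and the analysis finds it. A stricter variant using
the trained aligned model as probe (did 5 desk-scale epochs *imprint* the
hierarchy?) is computed and reported alongside; it is noisier, since
argmax over four correlated layer RDMs on 50 stimuli is a coarse
statistic.

Problem sizes throughout (200/50 images, 128 response features, small
channel widths, 10 seeds) are the package's desk-scale study conditions,
chosen once so the full experiment runs in minutes on one CPU.

## Determinism

Every generator and training loop is deterministic given its seed; a
single run seed derives all sub-seeds via `numpy.random.SeedSequence`.
Checkpoints record configuration and seeds; pipeline stages write
provenance files with a content hash of the resolved configuration.

## Known limitations

- The autodiff engine is float64 CPU-only and eager; it is sized for these
  models, not a general framework.
- The Control model shares the Adam trajectory structure but not identical
  batches' gradients with the aligned model; comparisons are seed-matched,
  not paired per gradient step.
- `improvement_ratio` is undefined for non-positive baselines by design;
  aggregate summaries skip undefined regions.
- The EEG simulator has no forward model (no electrode geometry, no
  temporal autocorrelation); its latency ramp is a caricature sufficient
  to give the timecourse analyses a recoverable structure.
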