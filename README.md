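# realign

Neural-data-driven alignment of recurrent vision models, with
representational similarity analysis (RSA) and object-dimension variance
partitioning — all runnable offline against a synthetic teacher cortex.

## The problem

Convolutional networks trained purely on images capture a lot of primate
visual cortex's representational structure, but substantial differences
remain. One way to close the gap is to train the network to *generate* the
brain's responses to the images it classifies: an image-to-fMRI encoding
head turns measured responses into a second training signal, without
committing to any fixed mapping between network layers and brain regions.
This package implements that multi-layer encoding alignment framework for a
CORnet-S-style recurrent classifier, the RSA machinery to evaluate whether
alignment worked, and a partial-correlation analysis of what changed inside
the model.

Real neuroimaging datasets are not required: a `synth` module simulates a
"teacher brain" (a frozen, category-trained network with noisy linear voxel
readouts per ROI, plus channel×time epoch data with a latency ramp) so that
every stage — training, evaluation, analysis — is testable end to end with
known ground truth.

## The model

The backbone is a four-stage recurrent convolutional classifier (stages
V1, V2, V4, IT; stage V2 and IT run twice, V4 four times, with shared
weights per stage). Each stage feeds a nonlinear 128-unit layer-encoder;
the four codes concatenate into a 512-unit multi-layer code, and a linear
head maps it to a 1,024-dimensional generated response vector
(PCA-reduced visual-cortex activity). Training minimises

    L_A = L_C + β · L_G

where `L_C` is categorical cross-entropy against teacher labels and

    L_G = MSE(S, Ŝ) + [1 − mean_i ρ(S_i, Ŝ_i)] + mean_{i≠j} ρ(S_i, Ŝ_j)

with `S` generated and `Ŝ` measured signals and ρ a Spearman correlation:
matched pairs are pulled together, mismatched pairs pushed apart (a batch
of N = 16 touches 256 pairs per step). `β = 0` gives the Control model —
identical data, classification gradient only. Since rank correlations have
zero gradient almost everywhere, training uses a differentiable surrogate
(Pearson on z-scored signals, or an optional soft-rank); evaluation always
reports exact Spearman.

Alignment is measured with RSA: correlation-distance RDMs per model layer
vs per-ROI voxel RDMs (or timepoint-wise pairwise-decoding RDMs for
epoch data), compared by Spearman correlation of their upper triangles,
with each region summarised by the maximum over layers and gains expressed
as `(aligned − baseline) / baseline`. Internal representations are
dissected by partial Spearman correlation of a layer RDM against 49
object-dimension RDMs, each controlling all remaining dimensions, with
r² the uniquely explained variance.

There is no pre-installed deep-learning framework in the target
environment, so the network and losses run on a compact numpy reverse-mode
autodiff engine (`realign.minidiff`), validated by numerical gradient
checks in the test suite.

## Worked example

Train an aligned model (β = 40) and its seed-matched Control against one
simulated teacher cortex (200 training images, 5 repeats, PCA to 128
features) and score both against held-out ROI RDMs:

```python
from realign.experiments import run_recovery

result = run_recovery(seed=0)
for roi in result.aligned_report.regions:
    print(roi, result.aligned_report.max_rho(roi),
          result.control_report.max_rho(roi),
          result.improvement_vs_control[roi]["ratio"])
```

Output (seed 0):

```
max-over-layers Spearman rho per ROI (held-out test images)
 ROI  aligned  control  improvement
  V1    0.564    0.432       30.6%
  V2    0.744    0.454       63.7%
  V3    0.768    0.376      104.2%
  V4    0.709    0.342      107.4%
 LOC    0.662    0.406       63.0%
mean improvement vs Control: 73.8%
best-matching layer, ROI V1: V1 | ROI LOC: IT
```

The aligned model out-scores the Control in every ROI: generating the
teacher's responses pulled the backbone's representational geometry toward
the teacher's. The last line shows hierarchy recovery — the analysis
assigns ROI V1 an earlier best-matching stage than LOC.

The same pipeline is scriptable from the shell:

```bash
realign simulate --workdir runs/demo --seed 3
realign train    --workdir runs/demo --seed 3
realign evaluate --workdir runs/demo --seed 3   # similarity + timecourse reports
realign analyze  --workdir runs/demo --seed 3   # dimension variance partitioning
```

Outputs land under `runs/demo/{data,checkpoints,reports}` as PNG + CSV,
HDF5, NPZ, JSON and TSV files; every stage writes a provenance record with
the resolved configuration and a parameter hash.

## Layout

- `src/realign/minidiff.py` — numpy autodiff engine (Tensor, conv/pool ops, Adam)
- `src/realign/backbone.py` — recurrent four-stage classifier with feature taps
- `src/realign/alignment.py` — encoder stack, losses, PCA reduction, training loop
- `src/realign/synth.py` — synthetic stimuli, teacher cortex, EEG-style epochs
- `src/realign/rsa.py` — RDM constructions, comparisons, similarity reports
- `src/realign/features.py` — partial-correlation variance partitioning
- `src/realign/experiments.py` — the seeded teacher-recovery study
- `src/realign/pipeline.py`, `cli.py`, `config.py` — the `realign` command

See `docs/methods.md` for the full methods note.
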