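"""Synthetic stimuli and teacher-brain responses.

This module emulates the statistical structure of visual-neuroimaging
experiments so the whole alignment pipeline is testable offline:

* :func:`generate_images` draws parametric coloured geometric shapes on
  textured backgrounds; the shape family, hue, size and stripe texture are
  category-determined, position/rotation/background are instance jitter, so
  categories are classifiable but non-trivial.
* A frozen "teacher" backbone stands in for a human visual cortex.  ROI
  responses are noisy linear readouts of its stage activations, with the
  hierarchy V1<-stage1, V2<-stage2, V3<-mean(stage2, stage3), V4<-stage3,
  LOC<-stage4.
* :func:`simulate_eeg` mixes the teacher's stages into channel x time epochs
  with a linear latency ramp: early timepoints are dominated by early stages
  and late timepoints by late stages.
* :func:`make_dimension_weights` produces per-stimulus object-dimension
  weight tables (dimension 0 tracks category identity by default).

Every generator is deterministic for a fixed seed.  Repeat noise is iid
Gaussian per repeat and feature; no hemodynamic or EEG forward model is
attempted.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np

from .backbone import STAGE_NAMES, Backbone, BackboneConfig, build_backbone, extract_features
from .datasets import ImageSet, NeuralDataset

__all__ = [
    "ROI_NAMES",
    "DEFAULT_LAYER_TO_ROI",
    "TeacherSpec",
    "generate_images",
    "make_teacher_spec",
    "simulate_voxels",
    "simulate_eeg",
    "average_repeats",
    "make_dimension_weights",
]

ROI_NAMES = ("V1", "V2", "V3", "V4", "LOC")

# Which teacher stages drive which ROI (V3 averages two adjacent stages,
# mirroring its intermediate position in the visual hierarchy).
DEFAULT_LAYER_TO_ROI: dict[str, tuple[str, ...]] = {
    "V1": ("V1",),
    "V2": ("V2",),
    "V3": ("V2", "V4"),
    "V4": ("V4",),
    "LOC": ("IT",),
}

# Stage-mixing profile at the earliest EEG timepoint (latest is its reverse).
_EEG_EARLY_PROFILE = np.array([0.70, 0.20, 0.07, 0.03])


# --------------------------------------------------------------------- images
def _draw_image(rng: np.random.Generator, size: int, category: int,
                n_categories: int) -> np.ndarray:
    """One HWC image in [0, 1] whose appearance is category-determined."""
    shape_kind = category % 5
    hue = (category * 0.6180339887) % 1.0
    scale = 0.30 + 0.35 * ((category // 5) % 4) / 3.0
    stripe_freq = 2.0 + 2.0 * ((category // 20) % 4)

    # Textured grey background (instance-specific).
    coarse = rng.normal(0.0, 1.0, size=(4, 4))
    bg = np.kron(coarse, np.ones((size // 4, size // 4)))[:size, :size]
    img = np.empty((size, size, 3))
    img[:] = (0.35 + 0.08 * np.tanh(bg))[:, :, None]

    # Instance jitter: position and rotation.
    cx, cy = rng.uniform(-0.25, 0.25, size=2)
    theta = rng.uniform(0, 2 * np.pi)
    ax = np.linspace(-1, 1, size)
    X, Y = np.meshgrid(ax, ax)
    u = np.cos(theta) * (X - cx) + np.sin(theta) * (Y - cy)
    v = -np.sin(theta) * (X - cx) + np.cos(theta) * (Y - cy)
    r = np.hypot(u, v)

    s = scale
    if shape_kind == 0:      # disc
        mask = r < s
    elif shape_kind == 1:    # square
        mask = np.maximum(np.abs(u), np.abs(v)) < s
    elif shape_kind == 2:    # triangle (pointing "up" in object coords)
        mask = (v > -s) & (v < s) & (np.abs(u) < (s - v) / 2)
    elif shape_kind == 3:    # annulus
        mask = (r < s) & (r > 0.45 * s)
    else:                    # cross
        mask = ((np.abs(u) < 0.35 * s) & (np.abs(v) < s)) | \
               ((np.abs(v) < 0.35 * s) & (np.abs(u) < s))

    stripes = 0.75 + 0.25 * np.sin(stripe_freq * np.pi * u / max(s, 1e-6))
    rgb = np.array(colorsys.hsv_to_rgb(hue, 0.85, 0.95))
    img[mask] = (stripes[mask, None] * rgb[None, :])
    return np.clip(img, 0.0, 1.0)


def generate_images(n: int, size: int, n_categories: int, seed: int) -> ImageSet:
    """Generate ``n`` synthetic stimuli spread evenly over categories.

    Categories are assigned round-robin so each has at least one image
    (``n`` must be >= ``n_categories``); with ``n`` a multiple of
    ``n_categories`` every category has exactly ``n / n_categories`` images.
    """
    if n <= 0 or size <= 0:
        raise ValueError("n and size must be positive")
    if n_categories < 2:
        raise ValueError("need at least two categories")
    if n < n_categories:
        raise ValueError("need at least one image per category")
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_categories
    pixels = np.stack([_draw_image(rng, size, int(c), n_categories) for c in labels])
    ids = [f"stim{i:05d}" for i in range(n)]
    split = np.asarray(["train"] * n, dtype=object)
    return ImageSet(ids, pixels, labels, split)


# -------------------------------------------------------------------- teacher
@dataclass
class TeacherSpec:
    """A frozen teacher backbone plus linear voxel readouts per ROI.

    ``readout_weights[roi]`` is a list of (stage_name, W) pairs; the ROI's
    noiseless response is the mean over contributing stages of the z-scored
    pooled stage features projected through W.  ``noise_sd`` scales the iid
    Gaussian repeat noise (readouts are normalised so the noiseless voxel
    variance is ~1 across stimuli).
    """

    teacher: Backbone
    readout_weights: dict[str, list[tuple[str, np.ndarray]]]
    noise_sd: float = 0.5
    layer_to_roi: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_TO_ROI))
    pool_grid: int = 2

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for roi, pairs in self.readout_weights.items():
            for _, w in pairs:
                if not np.all(np.isfinite(w)):
                    raise ValueError(f"non-finite readout weights for ROI {roi!r}")

    @property
    def rois(self) -> list[str]:
        return list(self.readout_weights)


def _pooled_stage_features(teacher: Backbone, pixels: np.ndarray,
                           pool_grid: int) -> dict[str, np.ndarray]:
    """Stage activations average-pooled to pool_grid**2 and z-scored per
    feature across stimuli (constant features stay zero)."""
    feats = extract_features(teacher, pixels)
    out = {}
    for name in STAGE_NAMES:
        a = feats[name]
        n, c, h, w = a.shape
        g = min(pool_grid, h, w)
        hb = np.linspace(0, h, g + 1).astype(int)
        wb = np.linspace(0, w, g + 1).astype(int)
        pooled = np.empty((n, c, g, g))
        for i in range(g):
            for j in range(g):
                pooled[:, :, i, j] = a[:, :, hb[i]:hb[i + 1], wb[j]:wb[j + 1]].mean(axis=(2, 3))
        flat = pooled.reshape(n, -1)
        mu = flat.mean(axis=0)
        sd = flat.std(axis=0)
        sd[sd == 0] = 1.0
        out[name] = (flat - mu) / sd
    return out


def make_teacher_spec(teacher: Backbone | None = None, n_vox_per_roi: int = 64,
                      noise_sd: float = 0.5, seed: int = 0,
                      layer_to_roi: dict[str, tuple[str, ...]] | None = None,
                      pool_grid: int = 2,
                      teacher_config: BackboneConfig | None = None) -> TeacherSpec:
    """Build a frozen teacher and random linear ROI readouts.

    If no teacher backbone is supplied, one is built from ``teacher_config``
    (or the default config) at a seed derived from ``seed``; its weights are
    random and never trained, which is all the downstream analyses need --
    random convolutional hierarchies already yield stage-specific geometry.
    """
    layer_to_roi = dict(layer_to_roi or DEFAULT_LAYER_TO_ROI)
    rng = np.random.default_rng(seed)
    if teacher is None:
        cfg = teacher_config or BackboneConfig()
        teacher = build_backbone(cfg, seed=int(rng.integers(2 ** 31)))
    # Feature widths per stage, for sizing the readouts.
    g = pool_grid
    widths = {}
    probe = np.zeros((1, teacher.config.input_size, teacher.config.input_size, 3))
    feats = extract_features(teacher, probe)
    for name in STAGE_NAMES:
        _, c, h, w = feats[name].shape
        gg = min(g, h, w)
        widths[name] = c * gg * gg
    readouts: dict[str, list[tuple[str, np.ndarray]]] = {}
    for roi, stages in layer_to_roi.items():
        pairs = []
        for stage in stages:
            d = widths[stage]
            w = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, n_vox_per_roi))
            pairs.append((stage, w))
        readouts[roi] = pairs
    return TeacherSpec(teacher=teacher, readout_weights=readouts, noise_sd=noise_sd,
                       layer_to_roi=layer_to_roi, pool_grid=pool_grid)


def teacher_roi_patterns(images: ImageSet, spec: TeacherSpec) -> dict[str, np.ndarray]:
    """Noiseless stimulus x voxel patterns per ROI (the generative signal)."""
    z = _pooled_stage_features(spec.teacher, images.pixels, spec.pool_grid)
    out = {}
    for roi, pairs in spec.readout_weights.items():
        acc = np.zeros((len(images), pairs[0][1].shape[1]))
        for stage, w in pairs:
            acc += z[stage] @ w
        out[roi] = acc / len(pairs)
    return out


def simulate_voxels(images: ImageSet, spec: TeacherSpec, n_repeats: int,
                    seed: int) -> NeuralDataset:
    """Simulate repeated voxel responses for the whole synthetic cortex.

    The feature axis concatenates the ROIs in ``spec`` order; boolean masks
    mark each ROI's block.  The noiseless component is identical across
    repeats; each repeat adds iid Gaussian noise of scale ``spec.noise_sd``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    missing = [r for r in spec.layer_to_roi if r not in spec.readout_weights]
    if missing:
        raise ValueError(f"layer_to_roi names ROIs without readouts: {missing}")
    patterns = teacher_roi_patterns(images, spec)
    rois = spec.rois
    blocks = [patterns[r] for r in rois]
    clean = np.concatenate(blocks, axis=1)
    n_features = clean.shape[1]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, spec.noise_sd, size=(len(images), n_repeats, n_features)) \
        if spec.noise_sd > 0 else np.zeros((len(images), n_repeats, n_features))
    responses = clean[:, None, :] + noise
    masks = {}
    start = 0
    for roi, block in zip(rois, blocks):
        mask = np.zeros(n_features, dtype=bool)
        mask[start:start + block.shape[1]] = True
        masks[roi] = mask
        start += block.shape[1]
    return NeuralDataset(list(images.ids), responses, masks, modality="voxel")


def eeg_stage_weights(n_timepoints: int) -> np.ndarray:
    """(n_stages, n_timepoints) mixing weights: linear ramp from an
    early-stage-dominated profile to its reverse."""
    alpha = np.linspace(0.0, 1.0, n_timepoints) if n_timepoints > 1 else np.array([0.5])
    early = _EEG_EARLY_PROFILE[:, None]
    late = _EEG_EARLY_PROFILE[::-1][:, None]
    return (1 - alpha[None, :]) * early + alpha[None, :] * late


def simulate_eeg(images: ImageSet, spec: TeacherSpec, n_channels: int = 17,
                 n_timepoints: int = 20, n_repeats: int = 80, seed: int = 0,
                 sfreq_hz: float = 100.0,
                 noise_sd: float | None = None) -> NeuralDataset:
    """Simulate channel x time epochs driven by the teacher's stages.

    Each stage is projected to the channel space through a fixed random map;
    per timepoint the stages are mixed with :func:`eeg_stage_weights`, so
    early timepoints carry mostly early-stage signal and late timepoints
    mostly late-stage signal.  Repeats add iid Gaussian noise of scale
    ``noise_sd`` (default 4.0): single-trial electrophysiology is noise
    dominated, and with this scale 16-trial pseudo-trial averages decode in
    the mid-accuracy range rather than saturating at ceiling.
    """
    if n_channels < 1 or n_timepoints < 1 or n_repeats < 1:
        raise ValueError("channel, timepoint and repeat counts must be >= 1")
    if noise_sd is None:
        noise_sd = 4.0
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    z = _pooled_stage_features(spec.teacher, images.pixels, spec.pool_grid)
    rng = np.random.default_rng(seed)
    proj = {}
    for name in STAGE_NAMES:
        d = z[name].shape[1]
        proj[name] = z[name] @ rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, n_channels))
    weights = eeg_stage_weights(n_timepoints)
    n = len(images)
    clean = np.zeros((n, n_channels, n_timepoints))
    for li, name in enumerate(STAGE_NAMES):
        clean += proj[name][:, :, None] * weights[li][None, None, :]
    clean_flat = clean.reshape(n, -1)
    noise = rng.normal(0.0, noise_sd, size=(n, n_repeats, clean_flat.shape[1])) \
        if noise_sd > 0 else np.zeros((n, n_repeats, clean_flat.shape[1]))
    responses = clean_flat[:, None, :] + noise
    return NeuralDataset(list(images.ids), responses, {}, modality="channel_time",
                         sfreq_hz=sfreq_hz, n_channels=n_channels,
                         n_timepoints=n_timepoints)


# ------------------------------------------------------------------ utilities
def average_repeats(data: NeuralDataset) -> NeuralDataset:
    """Average the repeat axis down to one repeat; metadata preserved."""
    if data.responses.shape[1] < 1:
        raise ValueError("empty repeat axis")
    return NeuralDataset(list(data.stimulus_ids),
                         data.responses.mean(axis=1, keepdims=True),
                         dict(data.roi_masks), modality=data.modality,
                         sfreq_hz=data.sfreq_hz, n_channels=data.n_channels,
                         n_timepoints=data.n_timepoints)


def make_dimension_weights(images: ImageSet, n_dims: int, seed: int,
                           category_dim: int | None = 0) -> np.ndarray:
    """Non-negative stimulus x n_dims object-dimension weights.

    Dimension ``category_dim`` (default 0) is driven by category identity:
    every image of a category shares a base weight plus small jitter, so its
    feature RDM has category-block structure.  Remaining dimensions are iid
    log-normal across stimuli.
    """
    if n_dims < 2:
        raise ValueError("n_dims must be >= 2 (partial correlation needs a covariate)")
    rng = np.random.default_rng(seed)
    n = len(images)
    weights = rng.lognormal(mean=0.0, sigma=0.5, size=(n, n_dims))
    if category_dim is not None:
        base = rng.uniform(0.3, 3.0, size=images.n_categories)
        weights[:, category_dim] = np.clip(
            base[images.labels] + rng.normal(0.0, 0.05, size=n), 0.0, None)
    return weights
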