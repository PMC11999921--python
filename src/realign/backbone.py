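"""Recurrent four-stage convolutional classifier.

The architecture follows the CORnet-S family: a feed-forward first stage
(7x7 stride-2 convolution, 3x3 stride-2 max-pool, 3x3 convolution) followed
by three weight-shared recurrent bottleneck stages, each traversed a fixed
number of times (default pass counts 1, 2, 4, 2 for stages V1, V2, V4, IT).
Spatial resolution halves once per stage; a pooled linear decoder produces
category logits.  Batch normalisation is omitted: at desk scale the plain
convolution + ReLU stack trains stably and keeps the parameter count and the
autodiff graph small.

Stage activations from the final recurrent pass are exposed for
representational analyses (flattened, post-ReLU, pre-pool by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .minidiff import Adam, Tensor, no_grad, softmax_cross_entropy

STAGE_NAMES = ("V1", "V2", "V4", "IT")

__all__ = [
    "STAGE_NAMES",
    "BackboneConfig",
    "Backbone",
    "build_backbone",
    "extract_features",
    "classify",
    "pretrain_classifier",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters.

    ``recurrence`` gives the number of passes through each stage's shared
    weights; the canonical setting runs stage V2 twice, V4 four times and IT
    twice.  ``stage_channels`` defaults small because large-scale image
    pre-training is out of scope.
    """

    stage_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    recurrence: tuple[int, int, int, int] = (1, 2, 4, 2)
    n_categories: int = 10
    input_size: int = 32

    def __post_init__(self):
        if len(self.stage_channels) != 4 or len(self.recurrence) != 4:
            raise ValueError("stage_channels and recurrence must have length 4")
        if any(c <= 0 for c in self.stage_channels):
            raise ValueError("stage channels must be positive")
        if any(r < 1 for r in self.recurrence):
            raise ValueError("recurrence counts must be >= 1")
        if self.n_categories < 2:
            raise ValueError("need at least two categories")
        if self.input_size < 16:
            raise ValueError("input_size must be >= 16 for the stride schedule")


def _he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    fan_in = int(np.prod(shape[1:]))
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    return Tensor(w, requires_grad=True)


class _RecurrentStage:
    """Weight-shared bottleneck stage.

    Each pass applies 1x1 -> 3x3 -> 1x1 convolutions with a residual
    connection; the 3x3 convolution strides by 2 on the first pass only, with
    a 1x1 strided projection on the skip path.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, passes: int):
        self.passes = passes
        self.conv_input_w = _he_init(rng, (out_ch, in_ch, 1, 1))
        self.conv_input_b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.skip_w = _he_init(rng, (out_ch, out_ch, 1, 1))
        self.skip_b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.conv1_w = _he_init(rng, (out_ch, out_ch, 1, 1))
        self.conv1_b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.conv2_w = _he_init(rng, (out_ch, out_ch, 3, 3))
        self.conv2_b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.conv3_w = _he_init(rng, (out_ch, out_ch, 1, 1))
        self.conv3_b = Tensor(np.zeros(out_ch), requires_grad=True)

    def parameters(self):
        return [self.conv_input_w, self.conv_input_b, self.skip_w, self.skip_b,
                self.conv1_w, self.conv1_b, self.conv2_w, self.conv2_b,
                self.conv3_w, self.conv3_b]

    def forward(self, x: Tensor, counter: list[int]) -> Tensor:
        x = x.conv2d(self.conv_input_w, self.conv_input_b)
        for t in range(self.passes):
            counter[0] += 1
            if t == 0:
                skip = x.conv2d(self.skip_w, self.skip_b, stride=2)
                stride = 2
            else:
                skip = x
                stride = 1
            y = x.conv2d(self.conv1_w, self.conv1_b).relu()
            y = y.conv2d(self.conv2_w, self.conv2_b, stride=stride, padding=1).relu()
            y = y.conv2d(self.conv3_w, self.conv3_b)
            x = (y + skip).relu()
        return x


class Backbone:
    """Four-stage recurrent convolutional classifier with feature taps."""

    def __init__(self, config: BackboneConfig, seed: int):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = config.stage_channels

        # Stage V1: feed-forward.
        self.v1_conv1_w = _he_init(rng, (c1, 3, 7, 7))
        self.v1_conv1_b = Tensor(np.zeros(c1), requires_grad=True)
        self.v1_conv2_w = _he_init(rng, (c1, c1, 3, 3))
        self.v1_conv2_b = Tensor(np.zeros(c1), requires_grad=True)

        self.stages = {
            "V2": _RecurrentStage(rng, c1, c2, config.recurrence[1]),
            "V4": _RecurrentStage(rng, c2, c3, config.recurrence[2]),
            "IT": _RecurrentStage(rng, c3, c4, config.recurrence[3]),
        }
        self.decoder_w = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / c4), size=(c4, config.n_categories)),
            requires_grad=True)
        self.decoder_b = Tensor(np.zeros(config.n_categories), requires_grad=True)
        # Executed-pass counters per stage, refreshed on every forward call.
        self.pass_counts: dict[str, int] = {}

    def parameters(self) -> list[Tensor]:
        params = [self.v1_conv1_w, self.v1_conv1_b, self.v1_conv2_w, self.v1_conv2_b]
        for stage in self.stages.values():
            params.extend(stage.parameters())
        params.extend([self.decoder_w, self.decoder_b])
        return params

    def forward(self, x: Tensor) -> tuple[dict[str, Tensor], Tensor]:
        """Run the network; return per-stage activations and logits.

        Stage activations are taken from the final recurrent pass,
        post-ReLU, pre-pool.
        """
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"input is {x.shape[2]}x{x.shape[3]}, backbone expects "
                f"{self.config.input_size}x{self.config.input_size}")
        feats: dict[str, Tensor] = {}
        counts = {"V1": 1}
        h = x.conv2d(self.v1_conv1_w, self.v1_conv1_b, stride=2, padding=3).relu()
        h = h.maxpool2d(kernel=3, stride=2, padding=1)
        h = h.conv2d(self.v1_conv2_w, self.v1_conv2_b, padding=1).relu()
        feats["V1"] = h
        for name in ("V2", "V4", "IT"):
            counter = [0]
            h = self.stages[name].forward(h, counter)
            counts[name] = counter[0]
            feats[name] = h
        pooled = h.avg_pool_to(1).reshape(h.shape[0], h.shape[1])
        logits = pooled @ self.decoder_w + self.decoder_b
        self.pass_counts = counts
        return feats, logits

    # ---------------------------------------------------------- serialization
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.array(state[f"p{i}"], dtype=np.float64)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {"config": asdict(self.config), "seed": self.seed}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "Backbone":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            cfg = meta["config"]
            cfg["stage_channels"] = tuple(cfg["stage_channels"])
            cfg["recurrence"] = tuple(cfg["recurrence"])
            model = cls(BackboneConfig(**cfg), seed=meta["seed"])
            model.load_state_dict({k: archive[k] for k in archive.files if k != "__meta__"})
        return model

    def clone(self) -> "Backbone":
        other = Backbone(self.config, self.seed)
        for p_other, p_self in zip(other.parameters(), self.parameters()):
            p_other.data = p_self.data.copy()
        return other


def build_backbone(config: BackboneConfig, seed: int) -> Backbone:
    """Construct a backbone with deterministic weight initialisation."""
    return Backbone(config, seed)


def _as_input_tensor(pixels: np.ndarray) -> Tensor:
    """HWC float images in [0,1] -> centred NCHW tensor."""
    x = np.transpose(np.asarray(pixels, dtype=np.float64), (0, 3, 1, 2))
    return Tensor(x - 0.5)


def extract_features(backbone: Backbone, pixels: np.ndarray,
                     batch_size: int = 64) -> dict[str, np.ndarray]:
    """Per-stage activations (final recurrent pass) plus logits, no gradients.

    Returns arrays keyed by stage name ("V1", "V2", "V4", "IT") with shape
    (n_stimuli, channels, height, width), and "logits".
    """
    outs: dict[str, list[np.ndarray]] = {name: [] for name in STAGE_NAMES}
    logits_parts = []
    with no_grad():
        for start in range(0, pixels.shape[0], batch_size):
            feats, logits = backbone.forward(_as_input_tensor(pixels[start:start + batch_size]))
            for name in STAGE_NAMES:
                outs[name].append(feats[name].data)
            logits_parts.append(logits.data)
    result = {name: np.concatenate(outs[name]) for name in STAGE_NAMES}
    result["logits"] = np.concatenate(logits_parts)
    return result


def classify(backbone: Backbone, pixels: np.ndarray) -> np.ndarray:
    """Per-stimulus category probabilities (softmax of the decoder logits)."""
    logits = extract_features(backbone, pixels)["logits"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def pretrain_classifier(backbone: Backbone, pixels: np.ndarray, labels: np.ndarray,
                        epochs: int = 8, lr: float = 1e-3, batch_size: int = 16,
                        seed: int = 0) -> list[float]:
    """Train the backbone on category labels; returns per-epoch mean loss.

    This supplies the image-trained starting point that a large-scale
    pre-trained checkpoint would otherwise provide.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(backbone.parameters(), lr=lr)
    n = pixels.shape[0]
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if idx.size < 2:
                continue
            _, logits = backbone.forward(_as_input_tensor(pixels[idx]))
            loss = softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history
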