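"""Multi-layer encoding alignment: encoder stack, losses, training.

Each backbone stage feeds a nonlinear layer-encoder (pooled activations ->
``encoder_dim`` units, ReLU); the four codes are concatenated into a
multi-layer visual code of width ``4 * encoder_dim`` and mapped by a linear
head to a generated response vector of width ``fmri_dim``.  The training
objective is

    L_A = L_C + beta * L_G

where ``L_C`` is categorical cross-entropy against teacher labels and
``L_G`` combines a mean-squared error with a contrastive correlation term:
matched (positive) generated/real signal pairs should correlate highly,
mismatched (negative) pairs should not.  With a batch of N stimuli the
contrastive part touches N positive and N(N-1) negative pairs (256 pairs at
N=16).  Setting ``beta = 0`` yields the Control model: identical
architecture and data order, classification gradient only.

Rank correlations have zero gradient almost everywhere, so training uses a
differentiable surrogate (Pearson correlation of z-scored signals by
default; a temperature-controlled soft-rank variant is available), while
evaluation and logging report the exact Spearman form.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .backbone import STAGE_NAMES, Backbone, _as_input_tensor
from .datasets import ImageSet
from .minidiff import Adam, Tensor, concat, no_grad, softmax_cross_entropy

__all__ = [
    "LossConfig",
    "EncoderStack",
    "AlignedModel",
    "attach_encoders",
    "classification_loss",
    "generation_loss",
    "alignment_loss",
    "teacher_labels",
    "train_alignment",
    "VoxelPCA",
    "reduce_voxels_pca",
    "contrastive_pair_count",
]

_EPS = 1e-12


@dataclass
class LossConfig:
    """Weights and switches of the alignment objective.

    beta = 0 defines the Control model (generation loss logged but
    gradient-inactive).
    """

    beta: float = 40.0
    use_mse: bool = True
    use_positive: bool = True
    use_negative: bool = True
    correlation_mode: str = "pearson_z"   # training surrogate: pearson_z | soft_rank
    soft_rank_temperature: float = 0.1

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.correlation_mode not in ("pearson_z", "soft_rank"):
            raise ValueError(f"unknown correlation_mode {self.correlation_mode!r}")


def contrastive_pair_count(batch_size: int) -> int:
    """Pairs touched by the contrastive term: N positive + N(N-1) negative."""
    return batch_size + batch_size * (batch_size - 1)


# ------------------------------------------------------------------- encoders
class EncoderStack:
    """Four per-stage encoders, a concatenated code, and the response head."""

    def __init__(self, stage_flat_dims: dict[str, int], encoder_dim: int,
                 fmri_dim: int, seed: int):
        if encoder_dim < 1 or fmri_dim < 1:
            raise ValueError("encoder_dim and fmri_dim must be >= 1")
        rng = np.random.default_rng(seed)
        self.encoder_dim = encoder_dim
        self.fmri_dim = fmri_dim
        self.stage_flat_dims = dict(stage_flat_dims)
        self.weights: dict[str, tuple[Tensor, Tensor]] = {}
        for name in STAGE_NAMES:
            d = stage_flat_dims[name]
            w = Tensor(rng.normal(0.0, np.sqrt(2.0 / d), size=(d, encoder_dim)),
                       requires_grad=True)
            b = Tensor(np.zeros(encoder_dim), requires_grad=True)
            self.weights[name] = (w, b)
        code_dim = 4 * encoder_dim
        self.head_w = Tensor(rng.normal(0.0, np.sqrt(1.0 / code_dim),
                                        size=(code_dim, fmri_dim)), requires_grad=True)
        self.head_b = Tensor(np.zeros(fmri_dim), requires_grad=True)

    @property
    def code_dim(self) -> int:
        return 4 * self.encoder_dim

    def parameters(self) -> list[Tensor]:
        params = []
        for w, b in self.weights.values():
            params.extend([w, b])
        params.extend([self.head_w, self.head_b])
        return params

    def forward(self, pooled: dict[str, Tensor]) -> tuple[Tensor, Tensor]:
        """Pooled stage features -> (multi-layer code, generated signals)."""
        codes = []
        for name in STAGE_NAMES:
            w, b = self.weights[name]
            codes.append((pooled[name] @ w + b).relu())
        code = concat(codes, axis=1)
        return code, code @ self.head_w + self.head_b


class AlignedModel:
    """Backbone + encoder stack producing (logits, generated signals)."""

    def __init__(self, backbone: Backbone, encoders: EncoderStack, pool_size: int):
        self.backbone = backbone
        self.encoders = encoders
        self.pool_size = pool_size

    def parameters(self) -> list[Tensor]:
        return self.backbone.parameters() + self.encoders.parameters()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (logits, generated signals, multi-layer code)."""
        feats, logits = self.backbone.forward(x)
        pooled = {}
        for name in STAGE_NAMES:
            f = feats[name]
            g = min(self.pool_size, f.shape[2], f.shape[3])
            p = f.avg_pool_to(g)
            pooled[name] = p.reshape(p.shape[0], -1)
        code, signals = self.encoders.forward(pooled)
        return logits, signals, code

    def generate(self, pixels: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Generated response vectors for HWC images, no gradients."""
        parts = []
        with no_grad():
            for start in range(0, pixels.shape[0], batch_size):
                _, signals, _ = self.forward(_as_input_tensor(pixels[start:start + batch_size]))
                parts.append(signals.data)
        return np.concatenate(parts)

    # ---------------------------------------------------------- serialization
    def save(self, path: str | Path, extra_meta: dict | None = None) -> None:
        meta = {"config": asdict(self.backbone.config), "seed": self.backbone.seed,
                "encoder_dim": self.encoders.encoder_dim,
                "fmri_dim": self.encoders.fmri_dim,
                "stage_flat_dims": self.encoders.stage_flat_dims,
                "pool_size": self.pool_size}
        if extra_meta:
            meta["extra"] = extra_meta
        arrays = {f"b{i}": p.data for i, p in enumerate(self.backbone.parameters())}
        arrays.update({f"e{i}": p.data for i, p in enumerate(self.encoders.parameters())})
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AlignedModel":
        from .backbone import BackboneConfig
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            cfg = meta["config"]
            cfg["stage_channels"] = tuple(cfg["stage_channels"])
            cfg["recurrence"] = tuple(cfg["recurrence"])
            backbone = Backbone(BackboneConfig(**cfg), seed=meta["seed"])
            encoders = EncoderStack(meta["stage_flat_dims"], meta["encoder_dim"],
                                    meta["fmri_dim"], seed=0)
            for i, p in enumerate(backbone.parameters()):
                p.data = np.array(archive[f"b{i}"])
            for i, p in enumerate(encoders.parameters()):
                p.data = np.array(archive[f"e{i}"])
        return cls(backbone, encoders, meta["pool_size"])


def attach_encoders(backbone: Backbone, encoder_dim: int = 128,
                    fmri_dim: int = 1024, pool_size: int = 2,
                    seed: int = 0) -> AlignedModel:
    """Attach fresh layer-encoders and a response head to a backbone."""
    probe = np.zeros((1, backbone.config.input_size, backbone.config.input_size, 3))
    with no_grad():
        feats, _ = backbone.forward(_as_input_tensor(probe))
    flat_dims = {}
    for name in STAGE_NAMES:
        _, c, h, w = feats[name].shape
        g = min(pool_size, h, w)
        flat_dims[name] = c * g * g
    encoders = EncoderStack(flat_dims, encoder_dim, fmri_dim, seed)
    return AlignedModel(backbone, encoders, pool_size)


# --------------------------------------------------------------------- losses
def classification_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of probabilities against labels."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim != 2 or labels.shape != (probs.shape[0],):
        raise ValueError("probs must be (n, k) with one label per row")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("labels out of range")
    picked = probs[np.arange(len(labels)), labels]
    if (picked <= 0).any():
        warnings.warn(f"zero probability on a true label; clamping at {_EPS}")
        picked = np.clip(picked, _EPS, None)
    return float(-np.log(picked).mean())


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, x)


def _zscore_rows(x: np.ndarray, warn_label: str) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        warnings.warn(f"constant {warn_label} row(s); their correlations are "
                      "defined as 0")
    sd[sd == 0] = np.inf        # constant rows z-score to 0 => rho contributions 0
    return (x - mu) / sd


def generation_loss(S: np.ndarray, S_hat: np.ndarray,
                    config: LossConfig | None = None) -> tuple[float, dict]:
    """Exact (evaluation-mode) generation loss with per-term breakdown.

    L_G = mean squared error + [1 - mean_i rho(S_i, S_hat_i)]
        + mean over ordered i != j pairs of rho(S_i, S_hat_j),

    with rho the Spearman correlation.  The MSE is averaged over samples and
    features so ``beta`` is comparable across response dimensionalities.
    Bounds: MSE >= 0, positive term in [0, 2], negative term in [-1, 1].
    """
    config = config or LossConfig()
    S = np.asarray(S, dtype=np.float64)
    S_hat = np.asarray(S_hat, dtype=np.float64)
    if S.shape != S_hat.shape:
        raise ValueError("generated and real signals must share a shape")
    n, d = S.shape
    if n < 2:
        raise ValueError("contrastive term needs a batch of >= 2")
    if d < 2:
        raise ValueError("correlation needs >= 2 features")
    zs = _zscore_rows(_rank_rows(S), "generated signal")
    zh = _zscore_rows(_rank_rows(S_hat), "real signal")
    rho = (zs @ zh.T) / d                       # rho[i, j] = spearman(S_i, S_hat_j)
    mse = float(((S - S_hat) ** 2).mean())
    positive = float(1.0 - np.trace(rho) / n)
    negative = float((rho.sum() - np.trace(rho)) / (n * (n - 1)))
    total = ((mse if config.use_mse else 0.0)
             + (positive if config.use_positive else 0.0)
             + (negative if config.use_negative else 0.0))
    return total, {"mse": mse, "positive": positive, "negative": negative,
                   "n_pairs": contrastive_pair_count(n)}


def _soft_rank(x: Tensor, temperature: float) -> Tensor:
    """Differentiable ranks via pairwise sigmoids, row-wise."""
    n, d = x.shape
    a = x.reshape(n, d, 1)
    b = x.reshape(n, 1, d)
    z = (a - b) * (1.0 / temperature)
    sig = 1.0 / (1.0 + (-z).exp())
    return sig.sum(axis=2) + 0.5


def _zscore_rows_t(x: Tensor) -> Tensor:
    mu = x.mean(axis=1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=1, keepdims=True)
    return centred / (var + _EPS).sqrt()


def generation_loss_train(S: Tensor, S_hat: np.ndarray,
                          config: LossConfig) -> tuple[Tensor, dict]:
    """Differentiable generation loss used by the training loop.

    The correlation is the configured surrogate (Pearson on z-scored
    signals, or soft-rank Spearman); the exact Spearman values belong to
    :func:`generation_loss`, which the history logger uses.
    """
    n, d = S.shape
    if n < 2:
        raise ValueError("contrastive term needs a batch of >= 2")
    target = np.asarray(S_hat, dtype=np.float64)
    diff = S - Tensor(target)
    mse = (diff * diff).mean()
    if config.correlation_mode == "soft_rank":
        zs = _zscore_rows_t(_soft_rank(S, config.soft_rank_temperature))
        zh_np = _zscore_rows(_rank_rows(target), "real signal")
    else:
        zs = _zscore_rows_t(S)
        zh_np = _zscore_rows(target, "real signal")
    rho = (zs @ Tensor(zh_np.T)) * (1.0 / d)
    eye = Tensor(np.eye(n))
    trace = (rho * eye).sum()
    positive = 1.0 - trace * (1.0 / n)
    negative = (rho.sum() - trace) * (1.0 / (n * (n - 1)))
    total = Tensor(0.0)
    if config.use_mse:
        total = total + mse
    if config.use_positive:
        total = total + positive
    if config.use_negative:
        total = total + negative
    breakdown = {"mse": mse.item(), "positive": positive.item(),
                 "negative": negative.item(), "n_pairs": contrastive_pair_count(n)}
    return total, breakdown


def alignment_loss(lc: float, lg: float, config: LossConfig) -> float:
    """Combined objective L_A = L_C + beta * L_G."""
    return lc + config.beta * lg


# ------------------------------------------------------------- teacher labels
def teacher_labels(control_backbone: Backbone, images: ImageSet) -> np.ndarray:
    """Argmax labels of a frozen reference model (ties -> lowest index)."""
    from .backbone import classify
    probs = classify(control_backbone, images.pixels)
    return probs.argmax(axis=1)


# ------------------------------------------------------------------------ PCA
class VoxelPCA:
    """PCA reduction of stimulus x voxel matrices, fit on training data only.

    Stores the training mean and components; optionally z-scores the reduced
    features with training statistics (recommended: stabilises the balance
    between the MSE and correlation terms of the loss).
    """

    def __init__(self, n_components: int, zscore: bool = True):
        self.n_components = n_components
        self.zscore = zscore
        self._pca: PCA | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def fit(self, train_matrix: np.ndarray) -> "VoxelPCA":
        train_matrix = np.asarray(train_matrix, dtype=np.float64)
        n, p = train_matrix.shape
        if self.n_components > min(n, p):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n_stimuli={n}, "
                f"n_voxels={p}), the binding constraint for PCA")
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        reduced = self._pca.fit_transform(train_matrix)
        self._mu = reduced.mean(axis=0)
        sd = reduced.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise RuntimeError("VoxelPCA must be fit before transform")
        reduced = self._pca.transform(np.asarray(matrix, dtype=np.float64))
        if self.zscore:
            reduced = (reduced - self._mu) / self._sd
        return reduced

    @property
    def explained_variance(self) -> np.ndarray:
        return self._pca.explained_variance_

    @property
    def components(self) -> np.ndarray:
        return self._pca.components_

    @property
    def mean(self) -> np.ndarray:
        return self._pca.mean_


def reduce_voxels_pca(train_matrix: np.ndarray, n_components: int,
                      zscore: bool = True) -> tuple[VoxelPCA, np.ndarray]:
    """Fit a PCA transform on the training matrix and reduce it."""
    pca = VoxelPCA(n_components, zscore=zscore).fit(train_matrix)
    return pca, pca.transform(train_matrix)


# ------------------------------------------------------------------- training
def train_alignment(model: AlignedModel, images: ImageSet, signals: np.ndarray,
                    labels: np.ndarray, config: LossConfig, epochs: int = 5,
                    lr: float = 2e-5, batch_size: int = 16,
                    seed: int = 0) -> list[dict]:
    """Train the aligned model; returns per-epoch loss history.

    ``signals`` is the repeat-averaged, dimensionality-reduced stimulus x
    fmri_dim target matrix; ``labels`` are the (teacher) category labels.
    Batches are shuffled under ``seed`` with Adam at a static learning rate.
    Incomplete final batches of size < 2 are dropped (the contrastive term
    is undefined there).  With ``beta = 0`` the generation loss is computed
    for logging only and contributes no gradient.
    """
    signals = np.asarray(signals, dtype=np.float64)
    if signals.shape != (len(images), model.encoders.fmri_dim):
        raise ValueError(
            f"signals shape {signals.shape} does not match (n_images, fmri_dim)="
            f"({len(images)}, {model.encoders.fmri_dim})")
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    history = []
    n = len(images)
    for epoch in range(epochs):
        order = rng.permutation(n)
        lcs, lgs, las = [], [], []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if idx.size < 2:
                continue
            x = _as_input_tensor(images.pixels[idx])
            logits, generated, _ = model.forward(x)
            lc = softmax_cross_entropy(logits, labels[idx])
            if config.beta > 0:
                lg, _ = generation_loss_train(generated, signals[idx], config)
                loss = lc + lg * config.beta
                lg_val = lg.item()
            else:
                lg_val, _ = generation_loss(generated.data, signals[idx], config)
                loss = lc
            opt.zero_grad()
            loss.backward()
            opt.step()
            lcs.append(lc.item())
            lgs.append(lg_val)
            las.append(lc.item() + config.beta * lg_val)
        history.append({"epoch": epoch, "lc": float(np.mean(lcs)),
                        "lg": float(np.mean(lgs)), "la": float(np.mean(las))})
    return history
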