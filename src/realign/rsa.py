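"""Representational similarity analysis.

RDM constructions:

* correlation distance between activation patterns (1 - Pearson),
* cross-validated pairwise decoding accuracy for channel x time epoch data
  (regularised linear discriminant on pseudo-trials),
* absolute weight differences along a single object dimension.

RDMs are compared by Spearman correlation of their vectorised upper
triangles (diagonal excluded).  Layer x region similarity tables are
summarised by the maximum over model layers per region -- no fixed
layer-to-region correspondence is assumed -- and alignment gains are
expressed as improvement ratios against a baseline model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import NeuralDataset

__all__ = [
    "RDM",
    "SimilarityReport",
    "rdm_from_patterns",
    "rdm_from_decoding",
    "rdm_from_weights",
    "compare_rdms",
    "layerwise_similarity",
    "improvement_ratio",
    "timecourse_similarity",
    "flatten_features",
]

_METHODS = ("one_minus_pearson", "decoding_accuracy", "abs_weight_diff")


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix over stimuli."""

    matrix: np.ndarray
    stimulus_ids: list[str]
    method: str
    context: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.stimulus_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("RDM must be square and aligned with stimulus ids")
        if self.method not in _METHODS:
            raise ValueError(f"unknown RDM method {self.method!r}")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("RDM diagonal must be zero")
        if self.method == "one_minus_pearson" and (
                self.matrix.min() < -1e-12 or self.matrix.max() > 2 + 1e-12):
            raise ValueError("correlation-distance entries must lie in [0, 2]")
        if self.method == "decoding_accuracy" and (
                self.matrix.min() < -1e-12 or self.matrix.max() > 1 + 1e-12):
            raise ValueError("decoding-accuracy entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def upper(self) -> np.ndarray:
        """Vectorised upper triangle, diagonal excluded."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    def save(self, path: str | Path) -> None:
        np.savez(path, matrix=self.matrix,
                 stimulus_ids=np.asarray(self.stimulus_ids, dtype="S"),
                 method=np.asarray(self.method), context=np.asarray(self.context))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.stimulus_ids,
                     columns=self.stimulus_ids).to_csv(path)

    @classmethod
    def load(cls, path: str | Path) -> "RDM":
        with np.load(path) as archive:
            return cls(matrix=archive["matrix"],
                       stimulus_ids=[s.decode() for s in archive["stimulus_ids"]],
                       method=str(archive["method"]), context=str(archive["context"]))


def _correlation_distance(patterns: np.ndarray) -> np.ndarray:
    """1 - Pearson between rows; constant rows get distance 1 (rho := 0)."""
    patterns = np.asarray(patterns, dtype=np.float64)
    sd = patterns.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn("constant activation pattern(s); their correlations are "
                      "defined as 0 (distance 1)")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(patterns)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return dist


def rdm_from_patterns(patterns: np.ndarray, stimulus_ids: list[str] | None = None,
                      context: str = "") -> RDM:
    """Correlation-distance RDM from a stimulus x feature pattern matrix."""
    patterns = np.asarray(patterns)
    if patterns.ndim != 2 or patterns.shape[0] < 2 or patterns.shape[1] < 2:
        raise ValueError("need >= 2 stimuli and >= 2 features")
    if stimulus_ids is None:
        stimulus_ids = [f"stim{i:05d}" for i in range(patterns.shape[0])]
    return RDM(_correlation_distance(patterns), list(stimulus_ids),
               "one_minus_pearson", context)


def rdm_from_weights(weights: np.ndarray, dim: int,
                     stimulus_ids: list[str] | None = None,
                     context: str = "") -> RDM:
    """Absolute weight-difference RDM along one object dimension."""
    weights = np.asarray(weights, dtype=np.float64)
    if not 0 <= dim < weights.shape[1]:
        raise IndexError(f"dimension {dim} out of range")
    w = weights[:, dim]
    matrix = np.abs(w[:, None] - w[None, :])
    if stimulus_ids is None:
        stimulus_ids = [f"stim{i:05d}" for i in range(len(w))]
    return RDM(matrix, list(stimulus_ids), "abs_weight_diff", context or f"dim{dim}")


# ---------------------------------------------------------- pairwise decoding
def _pseudo_trials(epochs_t: np.ndarray, n_pseudo: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Average shuffled repeats into n_pseudo pseudo-trials per condition."""
    n_cond, n_rep, d = epochs_t.shape
    order = rng.permutation(n_rep)
    groups = np.array_split(order, n_pseudo)
    return np.stack([epochs_t[:, g].mean(axis=1) for g in groups], axis=1)


def _pairwise_lda_accuracy(pseudo: np.ndarray, folds: list[np.ndarray],
                           shrinkage: float = 0.2) -> np.ndarray:
    """Cross-validated pairwise linear-discriminant accuracy.

    ``pseudo``: (n_cond, n_pseudo, d).  For every condition pair a Fisher
    discriminant is fit on the training pseudo-trials with a
    shrinkage-regularised pooled covariance, and accuracy is measured on the
    held-out pseudo-trials.  Returns the (n_cond, n_cond) accuracy matrix
    with a zero diagonal.
    """
    n_cond, n_pseudo, d = pseudo.shape
    iu, ju = np.triu_indices(n_cond, k=1)
    acc = np.zeros(len(iu))
    total = 0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n_pseudo), test_idx)
        train = pseudo[:, train_idx]            # (n_cond, n_train, d)
        mu = train.mean(axis=1)                  # (n_cond, d)
        centred = train - mu[:, None, :]
        denom = max(train.shape[1] - 1, 1)
        scatter = np.einsum("cnd,cne->cde", centred, centred) / denom
        sigma = 0.5 * (scatter[iu] + scatter[ju])            # (n_pairs, d, d)
        tr = np.trace(sigma, axis1=1, axis2=2) / d
        eye = np.eye(d)[None, :, :]
        sigma = (1 - shrinkage) * sigma + (shrinkage * tr)[:, None, None] * eye
        # Guard against zero-variance pairs (e.g. noiseless identical data).
        tiny = np.maximum(tr, 1e-12)
        sigma += (1e-9 * tiny)[:, None, None] * eye
        diff = mu[iu] - mu[ju]                                # (n_pairs, d)
        w = np.linalg.solve(sigma, diff[..., None])[..., 0]
        thresh = np.einsum("pd,pd->p", w, 0.5 * (mu[iu] + mu[ju]))
        test = pseudo[:, test_idx]               # (n_cond, n_test, d)
        proj_i = np.einsum("pd,pnd->pn", w, test[iu])
        proj_j = np.einsum("pd,pnd->pn", w, test[ju])
        acc += (proj_i > thresh[:, None]).sum(axis=1) + \
               (proj_j <= thresh[:, None]).sum(axis=1)
        total += 2 * test.shape[1]
    matrix = np.zeros((n_cond, n_cond))
    matrix[iu, ju] = acc / total
    matrix += matrix.T
    return matrix


def _decoding_folds(n_pseudo: int, cv_folds: int,
                    rng: np.random.Generator) -> list[np.ndarray]:
    if n_pseudo < 2:
        raise ValueError("need at least two pseudo-trials per condition")
    if cv_folds > n_pseudo:
        warnings.warn(f"reducing folds from {cv_folds} to {n_pseudo} "
                      "(not enough pseudo-trials)")
        cv_folds = n_pseudo
    order = rng.permutation(n_pseudo)
    return np.array_split(order, cv_folds)


def rdm_from_decoding(eeg: NeuralDataset, timepoint: int, cv_folds: int = 4,
                      seed: int = 0, pseudo_size: int = 16,
                      shrinkage: float = 0.2) -> RDM:
    """Decoding RDM at one timepoint of channel x time epoch data.

    Entry (i, j) is the cross-validated accuracy of a shrinkage linear
    discriminant separating conditions i and j from their channel vectors at
    ``timepoint``; repeats are averaged into pseudo-trials of roughly
    ``pseudo_size`` repeats each before the stratified split.
    """
    if eeg.modality != "channel_time":
        raise ValueError("decoding RDMs require channel_time data")
    if eeg.n_repeats < 2:
        raise ValueError("need >= 2 repeats per condition")
    epochs = eeg.epochs()[:, :, :, timepoint]    # (n_cond, n_rep, n_ch)
    rng = np.random.default_rng(seed)
    n_pseudo = max(2, min(eeg.n_repeats, max(cv_folds, eeg.n_repeats // pseudo_size)))
    pseudo = _pseudo_trials(epochs, n_pseudo, rng)
    folds = _decoding_folds(n_pseudo, cv_folds, rng)
    matrix = _pairwise_lda_accuracy(pseudo, folds, shrinkage)
    return RDM(matrix, list(eeg.stimulus_ids), "decoding_accuracy",
               context=f"t{timepoint}")


# ----------------------------------------------------------------- comparison
def compare_rdms(a: RDM, b: RDM) -> float:
    """Spearman correlation between the upper triangles of two RDMs."""
    if a.stimulus_ids != b.stimulus_ids:
        raise ValueError("RDMs must share stimulus ids in the same order")
    if a.n < 3:
        raise ValueError("need >= 3 stimuli for a meaningful rank correlation")
    rho, _ = stats.spearmanr(a.upper(), b.upper())
    return float(rho)


def flatten_features(features: np.ndarray) -> np.ndarray:
    """Flatten per-stimulus activation arrays to stimulus x feature."""
    features = np.asarray(features)
    return features.reshape(features.shape[0], -1)


@dataclass
class SimilarityReport:
    """Layer x region Spearman similarities with max-over-layer summaries."""

    table: pd.DataFrame                      # columns: model_layer, brain_context, spearman_rho
    region_summary: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "SimilarityReport":
        summary = {}
        for region, sub in table.groupby("brain_context", sort=False):
            best = sub.loc[sub["spearman_rho"].idxmax()]
            summary[str(region)] = {"rho": float(best["spearman_rho"]),
                                    "layer": str(best["model_layer"])}
        return cls(table=table.reset_index(drop=True), region_summary=summary)

    @property
    def regions(self) -> list[str]:
        return list(self.region_summary)

    def max_rho(self, region: str) -> float:
        return self.region_summary[region]["rho"]

    def argmax_layer(self, region: str) -> str:
        return self.region_summary[region]["layer"]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {"table": self.table.to_dict(orient="records"),
                   "region_summary": self.region_summary}
        path.write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "SimilarityReport":
        payload = json.loads(Path(path).read_text())
        return cls(table=pd.DataFrame(payload["table"]),
                   region_summary=payload["region_summary"])


def layerwise_similarity(model_features: dict[str, np.ndarray],
                         brain_rdms: dict[str, RDM],
                         stimulus_ids: list[str] | None = None) -> SimilarityReport:
    """Full layer x region similarity table plus max-over-layer summary.

    ``model_features`` maps layer names to per-stimulus activations (any
    shape; flattened per stimulus).  ``brain_rdms`` maps region names to
    RDMs over the same stimuli.
    """
    if not brain_rdms:
        raise ValueError("need at least one brain region RDM")
    first = next(iter(brain_rdms.values()))
    ids = stimulus_ids or first.stimulus_ids
    model_rdms = {layer: rdm_from_patterns(flatten_features(feats), ids, context=layer)
                  for layer, feats in model_features.items()}
    rows = []
    for region, brdm in brain_rdms.items():
        for layer, mrdm in model_rdms.items():
            rows.append({"model_layer": layer, "brain_context": region,
                         "spearman_rho": compare_rdms(mrdm, brdm)})
    return SimilarityReport.from_table(pd.DataFrame(rows))


def improvement_ratio(aligned: SimilarityReport,
                      baseline: SimilarityReport) -> dict[str, dict]:
    """(aligned - baseline) / baseline per region on the max-over-layer rho.

    Regions whose baseline rho is <= 0 are flagged as undefined rather than
    reported as an unstable number.
    """
    if set(aligned.regions) != set(baseline.regions):
        raise ValueError("reports cover different regions")
    out = {}
    for region in aligned.regions:
        base = baseline.max_rho(region)
        ali = aligned.max_rho(region)
        if base <= 0:
            out[region] = {"ratio": None, "defined": False}
        else:
            out[region] = {"ratio": (ali - base) / base, "defined": True}
    return out


def timecourse_similarity(model_features: dict[str, np.ndarray],
                          eeg: NeuralDataset, cv_folds: int = 4, seed: int = 0,
                          pseudo_size: int = 16) -> pd.DataFrame:
    """Layer x timepoint Spearman similarity against decoding RDMs.

    Returns a DataFrame indexed by model layer with one column per
    timepoint index.
    """
    ids = list(eeg.stimulus_ids)
    model_rdms = {layer: rdm_from_patterns(flatten_features(feats), ids, context=layer)
                  for layer, feats in model_features.items()}
    data = {}
    for t in range(eeg.n_timepoints):
        brdm = rdm_from_decoding(eeg, t, cv_folds=cv_folds, seed=seed + t,
                                 pseudo_size=pseudo_size)
        data[t] = {layer: compare_rdms(mrdm, brdm) for layer, mrdm in model_rdms.items()}
    frame = pd.DataFrame(data)
    frame.index.name = "model_layer"
    return frame
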