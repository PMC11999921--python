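"""Variance partitioning of a model RDM over object-dimension RDMs.

For each object dimension d, the analysis computes the partial Spearman
correlation between the vectorised model RDM and the dimension's feature
RDM, controlling for all remaining dimensions, and reports its square as
the variance in the model's representational geometry uniquely explained by
that dimension.

Partial Spearman is computed as partial Pearson on rank-transformed
vectorised RDMs (average ranks for ties): target and feature-d vectors are
each regressed on the remaining feature vectors (plus intercept) by least
squares, and the residuals are correlated.  Near-collinear covariates fall
back to a tiny ridge penalty and are flagged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import AlignedModel
from .backbone import extract_features
from .datasets import ImageSet
from .rsa import RDM, flatten_features, rdm_from_patterns, rdm_from_weights

__all__ = [
    "PartialCorrelationReport",
    "partial_rsa",
    "dimension_profile",
    "profile_difference",
]

_RIDGE = 1e-8


@dataclass
class PartialCorrelationReport:
    """Per-dimension partial correlation r and explained variance r^2."""

    table: pd.DataFrame      # columns: dimension, r, r2, ridge_flag
    context: str = ""

    def __post_init__(self):
        r = self.table["r"].to_numpy()
        if ((r < -1 - 1e-9) | (r > 1 + 1e-9)).any():
            raise ValueError("partial correlations must lie in [-1, 1]")

    @property
    def dimensions(self) -> list[str]:
        return list(self.table["dimension"])

    def r2(self, dimension: str) -> float:
        row = self.table.loc[self.table["dimension"] == dimension]
        return float(row["r2"].iloc[0])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps({"context": self.context,
                                        "table": self.table.to_dict(orient="records")},
                                       indent=2))
        else:
            self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "PartialCorrelationReport":
        path = Path(path)
        if path.suffix == ".json":
            payload = json.loads(path.read_text())
            return cls(pd.DataFrame(payload["table"]), payload.get("context", ""))
        return cls(pd.read_csv(path))


def _residualise(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, bool]:
    """Residual of y after least-squares regression on X (with intercept).

    Returns (residual, used_ridge).  A ridge fallback with a tiny penalty
    handles rank-deficient covariate blocks.
    """
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        gram = design.T @ design + _RIDGE * np.eye(design.shape[1])
        coef = np.linalg.solve(gram, design.T @ y)
        return y - design @ coef, True
    return y - design @ coef, False


def partial_rsa(target: RDM, feature_rdms: list[RDM],
                dimension_names: list[str] | None = None,
                context: str = "") -> PartialCorrelationReport:
    """Partial Spearman of the target RDM against each feature RDM.

    With a single feature RDM (no covariates) the partial correlation
    reduces to the plain Spearman correlation.
    """
    if not feature_rdms:
        raise ValueError("need at least one feature RDM")
    for f in feature_rdms:
        if f.stimulus_ids != target.stimulus_ids:
            raise ValueError("all RDMs must share stimulus ids in the same order")
    k = len(feature_rdms)
    if dimension_names is None:
        dimension_names = [f.context or f"dim{i:02d}" for i, f in enumerate(feature_rdms)]
    y = stats.rankdata(target.upper())
    F = np.column_stack([stats.rankdata(f.upper()) for f in feature_rdms])
    n_entries = len(y)
    if n_entries <= k + 2:
        raise ValueError("too few RDM entries for the number of covariates")
    rows = []
    for d in range(k):
        covariates = np.delete(F, d, axis=1)
        if covariates.shape[1] == 0:
            r = float(stats.pearsonr(y, F[:, d]).statistic)
            ridge = False
        else:
            ry, ridge_y = _residualise(y, covariates)
            rf, ridge_f = _residualise(F[:, d], covariates)
            ridge = ridge_y or ridge_f
            if ridge:
                warnings.warn(f"collinear covariates for dimension "
                              f"{dimension_names[d]!r}; ridge fallback used")
            sy, sf = ry.std(), rf.std()
            r = float(np.dot(ry - ry.mean(), rf - rf.mean()) / (len(y) * sy * sf)) \
                if sy > 0 and sf > 0 else 0.0
        r = float(np.clip(r, -1.0, 1.0))
        rows.append({"dimension": dimension_names[d], "r": r, "r2": r * r,
                     "ridge_flag": ridge})
    return PartialCorrelationReport(pd.DataFrame(rows), context=context)


def dimension_profile(model: AlignedModel, layer: str, images: ImageSet,
                      weights: np.ndarray, weight_ids: list[str] | None = None,
                      dimension_names: list[str] | None = None) -> PartialCorrelationReport:
    """Variance partitioning of one model layer over all object dimensions.

    Builds the layer's correlation-distance RDM from flattened stage
    activations, one absolute-difference feature RDM per weight column, and
    runs :func:`partial_rsa`.  Any stage (V1, V2, V4, IT) may be profiled.
    """
    weights = np.asarray(weights)
    ids = list(images.ids)
    if weight_ids is not None:
        lookup = {sid: i for i, sid in enumerate(weight_ids)}
        missing = [sid for sid in ids if sid not in lookup]
        if missing:
            raise ValueError(f"weight table missing stimulus ids: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        weights = weights[[lookup[sid] for sid in ids]]
    elif weights.shape[0] != len(ids):
        raise ValueError("weight table misaligned with image set")
    feats = extract_features(model.backbone, images.pixels)
    if layer not in feats:
        raise ValueError(f"unknown layer {layer!r}")
    target = rdm_from_patterns(flatten_features(feats[layer]), ids, context=layer)
    feature_rdms = [rdm_from_weights(weights, d, ids,
                                     context=(dimension_names[d] if dimension_names
                                              else f"dim{d:02d}"))
                    for d in range(weights.shape[1])]
    return partial_rsa(target, feature_rdms, dimension_names, context=layer)


def profile_difference(a: PartialCorrelationReport,
                       b: PartialCorrelationReport) -> pd.DataFrame:
    """Per-dimension r^2 differences (a - b), sorted descending.

    The returned frame has columns (dimension, r2_a, r2_b, delta_r2) plus a
    ``rank`` column; the first row is the dimension most enhanced in ``a``.
    """
    if a.dimensions != b.dimensions:
        raise ValueError("reports cover different dimensions")
    frame = pd.DataFrame({
        "dimension": a.dimensions,
        "r2_a": a.table["r2"].to_numpy(),
        "r2_b": b.table["r2"].to_numpy(),
    })
    frame["delta_r2"] = frame["r2_a"] - frame["r2_b"]
    frame = frame.sort_values("delta_r2", ascending=False).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
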