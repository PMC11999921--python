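"""Run configuration: YAML schema, validation, provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["SyntheticConfig", "AlignmentConfig", "EvaluationConfig", "RunConfig"]


def _coerce(cls, payload: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**payload)


@dataclass
class SyntheticConfig:
    n_train: int = 200
    n_test: int = 50
    n_categories: int = 10
    image_size: int = 32
    n_repeats: int = 5
    noise_sd: float = 0.5
    n_vox_per_roi: int = 64
    teacher_pretrain_epochs: int = 20
    teacher_pool_grid: int = 4
    eeg_channels: int = 17
    eeg_timepoints: int = 20
    eeg_repeats: int = 80
    eeg_sfreq_hz: float = 100.0
    eeg_noise_sd: float = 4.0
    n_dims: int = 49

    def validate(self) -> None:
        if self.n_train < self.n_categories or self.n_categories < 2:
            raise ValueError("need n_train >= n_categories >= 2")
        if self.n_test < 3:
            raise ValueError("need at least 3 test images for RDM comparisons")
        if self.noise_sd < 0 or self.n_repeats < 1:
            raise ValueError("invalid noise/repeat settings")
        if self.n_dims < 2:
            raise ValueError("n_dims must be >= 2")


@dataclass
class AlignmentConfig:
    beta: float = 40.0
    lr: float = 3e-3
    epochs: int = 5
    batch_size: int = 16
    encoder_dim: int = 32
    fmri_dim: int = 128
    pool_size: int = 2
    surrogate: str = "pearson_z"
    pca_zscore: bool = False
    pretrain_epochs: int = 8
    pretrain_lr: float = 1e-3
    stage_channels: tuple = (8, 16, 16, 32)

    def validate(self) -> None:
        if self.beta < 0 or self.batch_size < 2 or self.epochs < 1:
            raise ValueError("invalid alignment settings")
        if self.surrogate not in ("pearson_z", "soft_rank"):
            raise ValueError(f"unknown surrogate {self.surrogate!r}")
        self.stage_channels = tuple(self.stage_channels)


@dataclass
class EvaluationConfig:
    cv_folds: int = 4
    pseudo_size: int = 16
    rois: tuple = ("V1", "V2", "V3", "V4", "LOC")

    def validate(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        self.rois = tuple(self.rois)


@dataclass
class RunConfig:
    """Complete pipeline configuration with a single run seed."""

    seed: int = 0
    workdir: str = "runs/default"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def validate(self) -> "RunConfig":
        self.synthetic.validate()
        self.alignment.validate()
        self.evaluation.validate()
        if self.alignment.fmri_dim > self.synthetic.n_train:
            raise ValueError("fmri_dim cannot exceed the number of training "
                             "stimuli (PCA constraint)")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload, **overrides)

    @classmethod
    def from_dict(cls, payload: dict, **overrides) -> "RunConfig":
        payload = dict(payload)
        payload.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(
            seed=int(payload.get("seed", 0)),
            workdir=str(payload.get("workdir", "runs/default")),
            synthetic=_coerce(SyntheticConfig, payload.get("synthetic", {})),
            alignment=_coerce(AlignmentConfig, payload.get("alignment", {})),
            evaluation=_coerce(EvaluationConfig, payload.get("evaluation", {})),
        )
        return cfg.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alignment"]["stage_channels"] = list(self.alignment.stage_channels)
        d["evaluation"]["rois"] = list(self.evaluation.rois)
        return d

    def parameter_hash(self) -> str:
        """Content hash of everything that determines the outputs (not paths)."""
        payload = self.to_dict()
        payload.pop("workdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
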