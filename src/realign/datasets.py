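"""In-memory containers and on-disk formats for stimuli and neural responses.

``ImageSet`` holds a stimulus stream (pixels in [0, 1], integer category
labels, train/test split tags) and round-trips to a directory of PNG files
plus a ``manifest.csv``.  ``NeuralDataset`` holds a stimulus x repeat x
feature response array with named ROI masks; voxel data and flattened
channel x time epoch data share the container, distinguished by
``modality``.  Both round-trip to HDF5.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

__all__ = ["ImageSet", "NeuralDataset", "write_weights_tsv", "read_weights_tsv"]


@dataclass
class ImageSet:
    """A collection of same-sized images with ids, labels and split tags."""

    ids: list[str]
    pixels: np.ndarray  # (n, h, w, 3), float in [0, 1]
    labels: np.ndarray  # (n,) int
    split: np.ndarray   # (n,) str, "train" | "test"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.split = np.asarray(self.split, dtype=object)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("stimulus ids must be unique")
        if self.pixels.ndim != 4 or self.pixels.shape[0] != n:
            raise ValueError("pixels must be (n, h, w, c) aligned with ids")
        if self.labels.shape != (n,) or self.split.shape != (n,):
            raise ValueError("labels and split must align with ids")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_categories(self) -> int:
        return int(self.labels.max()) + 1

    def subset(self, index: np.ndarray) -> "ImageSet":
        index = np.asarray(index)
        return ImageSet([self.ids[i] for i in index], self.pixels[index],
                        self.labels[index], self.split[index])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, sid in enumerate(self.ids):
            fname = f"{sid}.png"
            arr = np.clip(self.pixels[i] * 255.0, 0, 255).round().astype(np.uint8)
            Image.fromarray(arr).save(directory / fname)
            rows.append((sid, fname, int(self.labels[i]), str(self.split[i])))
        with open(directory / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "filename", "label", "split"])
            writer.writerows(rows)

    @classmethod
    def load(cls, directory: str | Path) -> "ImageSet":
        directory = Path(directory)
        ids, pixels, labels, split = [], [], [], []
        with open(directory / "manifest.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                ids.append(row["id"])
                arr = np.asarray(Image.open(directory / row["filename"]).convert("RGB"))
                pixels.append(arr.astype(np.float64) / 255.0)
                labels.append(int(row["label"]))
                split.append(row["split"])
        return cls(ids, np.stack(pixels), np.asarray(labels), np.asarray(split, dtype=object))


@dataclass
class NeuralDataset:
    """Stimulus x repeat x feature responses with named ROI masks.

    For ``modality="channel_time"`` the feature axis is the flattened
    channel x timepoint grid (channel-major) and the sampling metadata is
    populated.
    """

    stimulus_ids: list[str]
    responses: np.ndarray           # (n_stim, n_repeats, n_features)
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)
    modality: str = "voxel"
    sfreq_hz: float | None = None
    n_channels: int | None = None
    n_timepoints: int | None = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.responses.ndim != 3:
            raise ValueError("responses must be (n_stim, n_repeats, n_features)")
        if self.responses.shape[0] != len(self.stimulus_ids):
            raise ValueError("responses misaligned with stimulus ids")
        if self.responses.shape[1] < 1:
            raise ValueError("need at least one repeat")
        if self.modality not in ("voxel", "channel_time"):
            raise ValueError(f"unknown modality {self.modality!r}")
        nf = self.responses.shape[2]
        for name, mask in self.roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (nf,):
                raise ValueError(f"ROI mask {name!r} has wrong length")
            if not mask.any():
                raise ValueError(f"ROI mask {name!r} is empty")
            self.roi_masks[name] = mask
        if self.modality == "channel_time":
            if self.n_channels is None or self.n_timepoints is None:
                raise ValueError("channel_time data needs n_channels and n_timepoints")
            if self.n_channels * self.n_timepoints != nf:
                raise ValueError("feature axis must equal n_channels * n_timepoints")

    @property
    def n_repeats(self) -> int:
        return self.responses.shape[1]

    @property
    def n_features(self) -> int:
        return self.responses.shape[2]

    def roi_responses(self, roi: str) -> np.ndarray:
        return self.responses[:, :, self.roi_masks[roi]]

    def epochs(self) -> np.ndarray:
        """channel_time responses as (n_stim, n_repeats, n_channels, n_timepoints)."""
        if self.modality != "channel_time":
            raise ValueError("epochs() requires channel_time data")
        n, r, _ = self.responses.shape
        return self.responses.reshape(n, r, self.n_channels, self.n_timepoints)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("responses", data=self.responses)
            fh.create_dataset("stimulus_ids",
                              data=np.asarray(self.stimulus_ids, dtype="S"))
            grp = fh.create_group("rois")
            for name, mask in self.roi_masks.items():
                grp.create_dataset(name, data=mask)
            fh.attrs["modality"] = self.modality
            if self.modality == "channel_time":
                fh.attrs["sfreq_hz"] = self.sfreq_hz
                fh.attrs["n_channels"] = self.n_channels
                fh.attrs["n_timepoints"] = self.n_timepoints

    @classmethod
    def load(cls, path: str | Path) -> "NeuralDataset":
        with h5py.File(path, "r") as fh:
            modality = fh.attrs["modality"]
            kwargs = {}
            if modality == "channel_time":
                kwargs = {"sfreq_hz": float(fh.attrs["sfreq_hz"]),
                          "n_channels": int(fh.attrs["n_channels"]),
                          "n_timepoints": int(fh.attrs["n_timepoints"])}
            return cls(
                stimulus_ids=[s.decode() for s in fh["stimulus_ids"][()]],
                responses=fh["responses"][()],
                roi_masks={name: fh["rois"][name][()].astype(bool) for name in fh["rois"]},
                modality=str(modality), **kwargs)


def write_weights_tsv(path: str | Path, stimulus_ids: list[str],
                      weights: np.ndarray, dim_names: list[str] | None = None) -> None:
    """Write a stimulus x dimension weight table as TSV with a header row."""
    weights = np.asarray(weights)
    if dim_names is None:
        dim_names = [f"dim{j:02d}" for j in range(weights.shape[1])]
    with open(path, "w", newline="") as fh:
        fh.write("stimulus_id\t" + "\t".join(dim_names) + "\n")
        for sid, row in zip(stimulus_ids, weights):
            fh.write(sid + "\t" + "\t".join(f"{v:.8f}" for v in row) + "\n")


def read_weights_tsv(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a weight TSV; returns (stimulus_ids, weights, dimension names)."""
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        dim_names = header[1:]
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return ids, np.asarray(rows), dim_names
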