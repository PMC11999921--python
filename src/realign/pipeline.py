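"""End-to-end seeded pipeline: simulate -> train -> evaluate -> analyze.

Each stage reads and writes files under the configured working directory
(``data/``, ``checkpoints/``, ``reports/``) so stages can be rerun and
inspected independently.  All randomness derives from the single run seed;
every stage logs the resolved configuration and a parameter hash, and
records them in a provenance file next to its outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .alignment import (AlignedModel, LossConfig, attach_encoders,
                        reduce_voxels_pca, teacher_labels, train_alignment)
from .backbone import (Backbone, BackboneConfig, build_backbone, extract_features,
                       pretrain_classifier)
from .config import RunConfig
from .datasets import ImageSet, NeuralDataset, read_weights_tsv, write_weights_tsv
from .features import dimension_profile, profile_difference
from .rsa import improvement_ratio, layerwise_similarity, timecourse_similarity
from .synth import (average_repeats, generate_images, make_dimension_weights,
                    make_teacher_spec, simulate_eeg, simulate_voxels)

log = logging.getLogger("realign")

_LAYERS = ("V1", "V2", "V4", "IT")


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in (np.random.SeedSequence(seed).generate_state(n) % (2 ** 31))]


def _dirs(config: RunConfig) -> dict[str, Path]:
    work = Path(config.workdir)
    return {"work": work, "data": work / "data",
            "checkpoints": work / "checkpoints", "reports": work / "reports"}


def _log_provenance(config: RunConfig, stage: str, directory: Path) -> None:
    log.info("stage=%s seed=%d hash=%s config=%s", stage, config.seed,
             config.parameter_hash(), json.dumps(config.to_dict(), sort_keys=True))
    directory.mkdir(parents=True, exist_ok=True)
    (directory / f"provenance_{stage}.json").write_text(json.dumps(
        {"stage": stage, "seed": config.seed,
         "parameter_hash": config.parameter_hash(),
         "config": config.to_dict()}, indent=2))


def _backbone_config(config: RunConfig) -> BackboneConfig:
    return BackboneConfig(stage_channels=config.alignment.stage_channels,
                          n_categories=config.synthetic.n_categories,
                          input_size=config.synthetic.image_size)


def cmd_simulate(config: RunConfig, force: bool = False) -> dict[str, Path]:
    """Generate the synthetic study: images, voxel and EEG data, weights."""
    dirs = _dirs(config)
    data = dirs["data"]
    if data.exists() and any(data.iterdir()) and not force:
        raise FileExistsError(f"{data} is not empty; pass force=True/--force to overwrite")
    data.mkdir(parents=True, exist_ok=True)
    syn = config.synthetic
    s_img, s_teacher, s_vox_tr, s_vox_te, s_eeg, s_dims = _sub_seeds(config.seed, 6)

    images = generate_images(syn.n_train + syn.n_test, syn.image_size,
                             syn.n_categories, s_img)
    images.split[syn.n_train:] = "test"
    images.save(data / "images")
    train_images = images.subset(np.arange(syn.n_train))
    test_images = images.subset(np.arange(syn.n_train, len(images)))

    teacher = build_backbone(_backbone_config(config), seed=s_teacher)
    if syn.teacher_pretrain_epochs > 0:
        pretrain_classifier(teacher, train_images.pixels, train_images.labels,
                            epochs=syn.teacher_pretrain_epochs,
                            lr=config.alignment.pretrain_lr,
                            batch_size=config.alignment.batch_size, seed=s_teacher)
    spec = make_teacher_spec(teacher=teacher, n_vox_per_roi=syn.n_vox_per_roi,
                             noise_sd=syn.noise_sd, seed=s_teacher,
                             pool_grid=syn.teacher_pool_grid)

    simulate_voxels(train_images, spec, syn.n_repeats, s_vox_tr).save(data / "train_voxels.h5")
    simulate_voxels(test_images, spec, syn.n_repeats, s_vox_te).save(data / "test_voxels.h5")
    simulate_eeg(test_images, spec, syn.eeg_channels, syn.eeg_timepoints,
                 syn.eeg_repeats, s_eeg, syn.eeg_sfreq_hz,
                 noise_sd=syn.eeg_noise_sd).save(data / "eeg.h5")
    weights = make_dimension_weights(test_images, syn.n_dims, s_dims)
    write_weights_tsv(data / "weights.tsv", list(test_images.ids), weights)
    dirs["checkpoints"].mkdir(parents=True, exist_ok=True)
    teacher.save(dirs["checkpoints"] / "teacher.npz")
    _log_provenance(config, "simulate", data)
    return {"data": data}


def _load_images(config: RunConfig) -> tuple[ImageSet, ImageSet]:
    data = _dirs(config)["data"]
    images = ImageSet.load(data / "images")
    is_train = images.split == "train"
    return images.subset(np.flatnonzero(is_train)), images.subset(np.flatnonzero(~is_train))


def cmd_train(config: RunConfig) -> dict[str, Path]:
    """Pretrain the baseline, then train aligned (beta) and Control (beta=0)."""
    dirs = _dirs(config)
    data, ckpt = dirs["data"], dirs["checkpoints"]
    for fname in ("train_voxels.h5", "images/manifest.csv"):
        if not (data / fname).exists():
            raise FileNotFoundError(f"missing {data / fname}; run simulate first")
    ckpt.mkdir(parents=True, exist_ok=True)
    ali = config.alignment
    s_init, s_enc, s_train = _sub_seeds(config.seed + 1, 3)

    train_images, _ = _load_images(config)
    train_data = NeuralDataset.load(data / "train_voxels.h5")
    vc = average_repeats(train_data).responses[:, 0, :]
    if ali.fmri_dim > min(vc.shape):
        raise ValueError(f"fmri_dim={ali.fmri_dim} exceeds dataset limits {vc.shape}")
    _, signals = reduce_voxels_pca(vc, ali.fmri_dim, zscore=ali.pca_zscore)

    base = build_backbone(_backbone_config(config), seed=s_init)
    pretrain_classifier(base, train_images.pixels, train_images.labels,
                        epochs=ali.pretrain_epochs, lr=ali.pretrain_lr,
                        batch_size=ali.batch_size, seed=s_init)
    base.save(ckpt / "baseline.npz")
    labels = teacher_labels(base, train_images)

    histories = {}
    for name, beta in (("aligned", ali.beta), ("control", 0.0)):
        model = attach_encoders(base.clone(), ali.encoder_dim, ali.fmri_dim,
                                ali.pool_size, seed=s_enc)
        histories[name] = train_alignment(
            model, train_images, signals, labels,
            LossConfig(beta=beta, correlation_mode=ali.surrogate),
            epochs=ali.epochs, lr=ali.lr, batch_size=ali.batch_size, seed=s_train)
        model.save(ckpt / f"{name}.npz", extra_meta={"beta": beta})
    (ckpt / "history.json").write_text(json.dumps(histories, indent=2))
    _log_provenance(config, "train", ckpt)
    return {"checkpoints": ckpt}


def _load_models(config: RunConfig) -> dict[str, Backbone]:
    ckpt = _dirs(config)["checkpoints"]
    models = {}
    for name in ("aligned", "control"):
        path = ckpt / f"{name}.npz"
        if not path.exists():
            raise FileNotFoundError(f"missing checkpoint {path}; run train first")
        models[name] = AlignedModel.load(path).backbone
    base_path = ckpt / "baseline.npz"
    if not base_path.exists():
        raise FileNotFoundError(f"missing checkpoint {base_path}; run train first")
    models["baseline"] = Backbone.load(base_path)
    return models


def cmd_evaluate(config: RunConfig) -> dict[str, Path]:
    """Region-wise and timepoint-wise similarity reports plus improvements."""
    dirs = _dirs(config)
    data, reports = dirs["data"], dirs["reports"]
    reports.mkdir(parents=True, exist_ok=True)
    _, test_images = _load_images(config)
    test_data = NeuralDataset.load(data / "test_voxels.h5")
    eeg = NeuralDataset.load(data / "eeg.h5")
    models = _load_models(config)
    s_eval = _sub_seeds(config.seed + 2, 1)[0]

    averaged = average_repeats(test_data)
    from .rsa import rdm_from_patterns
    brain_rdms = {roi: rdm_from_patterns(averaged.roi_responses(roi)[:, 0, :],
                                         list(test_images.ids), context=roi)
                  for roi in config.evaluation.rois}

    sim_reports = {}
    for name, backbone in models.items():
        feats = extract_features(backbone, test_images.pixels)
        layer_feats = {layer: feats[layer] for layer in _LAYERS}
        rep = layerwise_similarity(layer_feats, brain_rdms, list(test_images.ids))
        rep.save(reports / f"similarity_{name}.json")
        sim_reports[name] = rep
        tc = timecourse_similarity(layer_feats, eeg,
                                   cv_folds=config.evaluation.cv_folds,
                                   seed=s_eval,
                                   pseudo_size=config.evaluation.pseudo_size)
        tc.to_csv(reports / f"timecourse_{name}.csv")

    for other in ("control", "baseline"):
        ratios = improvement_ratio(sim_reports["aligned"], sim_reports[other])
        (reports / f"improvement_vs_{other}.json").write_text(json.dumps(ratios, indent=2))
    _log_provenance(config, "evaluate", reports)
    return {"reports": reports}


def cmd_analyze(config: RunConfig) -> dict[str, Path]:
    """Object-dimension variance partitioning per layer, plus differences."""
    dirs = _dirs(config)
    data, ckpt, reports = dirs["data"], dirs["checkpoints"], dirs["reports"]
    reports.mkdir(parents=True, exist_ok=True)
    _, test_images = _load_images(config)
    weight_ids, weights, dim_names = read_weights_tsv(data / "weights.tsv")
    models = {}
    for name in ("aligned", "control"):
        path = ckpt / f"{name}.npz"
        if not path.exists():
            raise FileNotFoundError(f"missing checkpoint {path}; run train first")
        models[name] = AlignedModel.load(path)

    for layer in _LAYERS:
        profiles = {}
        for name, model in models.items():
            prof = dimension_profile(model, layer, test_images, weights,
                                     weight_ids, dim_names)
            prof.save(reports / f"dimensions_{name}_{layer}.csv")
            profiles[name] = prof
        diff = profile_difference(profiles["aligned"], profiles["control"])
        diff.to_csv(reports / f"dimensions_diff_{layer}.csv", index=False)
    _log_provenance(config, "analyze", reports)
    return {"reports": reports}
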