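"""Shared fixtures: all data is generated programmatically and seeded."""

import numpy as np
import pytest

from realign.backbone import BackboneConfig, build_backbone, pretrain_classifier
from realign.synth import generate_images, make_teacher_spec

SMALL_CHANNELS = (8, 16, 16, 32)


@pytest.fixture(scope="session")
def small_config():
    return BackboneConfig(stage_channels=SMALL_CHANNELS, n_categories=6,
                          input_size=32)


@pytest.fixture(scope="session")
def images60(small_config):
    """60 synthetic stimuli, 6 categories, 32 px."""
    return generate_images(60, 32, 6, seed=11)


@pytest.fixture(scope="session")
def backbone6(small_config):
    return build_backbone(small_config, seed=21)


@pytest.fixture(scope="session")
def trained_backbone6(small_config, images60):
    bb = build_backbone(small_config, seed=22)
    pretrain_classifier(bb, images60.pixels, images60.labels, epochs=6,
                        lr=1e-3, seed=22)
    return bb


@pytest.fixture(scope="session")
def teacher_spec6(trained_backbone6):
    """Teacher spec built on the session's trained backbone."""
    return make_teacher_spec(teacher=trained_backbone6, n_vox_per_roi=32,
                             noise_sd=0.5, seed=31, pool_grid=4)
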