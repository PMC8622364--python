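"""Shared fixtures: synthetic datasets at three scales.

micro  — 4+4 slides of 512 px: fast plumbing tests.
midi   — 10+10 slides of 1024 px: generator-statistics tests.
desk   — 23+23 slides of 2048 px split 20/6/20: end-to-end training.
All are generated once per session into pytest temp directories.
"""

from __future__ import annotations

import pytest

from histomine.model import BackboneConfig
from histomine.synthetic import SynthConfig, generate_dataset
from histomine.tiling import load_labeled_slides
from histomine.training import TrainingConfig


def desk_training_config(seed: int) -> TrainingConfig:
    """Desk-scale two-phase training settings (tile 128 / stride 64)."""
    return TrainingConfig(tile_size=128, train_stride=64, stop_patience=4,
                          max_epochs=30, seed=seed)


def desk_backbone_config() -> BackboneConfig:
    return BackboneConfig(architecture="tiny_cnn", input_size=32)


@pytest.fixture(scope="session")
def micro_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("micro")
    cfg = SynthConfig(n_positive=4, n_negative=4, slide_size=512,
                      n_fragments=(2, 3), seed=42)
    manifest = generate_dataset(cfg, out)
    return manifest


@pytest.fixture(scope="session")
def micro_slides(micro_dataset):
    return load_labeled_slides(micro_dataset)


@pytest.fixture(scope="session")
def midi_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("midi")
    cfg = SynthConfig(n_positive=10, n_negative=10, slide_size=1024, seed=7)
    manifest = generate_dataset(cfg, out)
    return manifest


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("desk")
    cfg = SynthConfig(n_positive=23, n_negative=23, slide_size=2048, seed=2024)
    manifest = generate_dataset(cfg, out,
                                split_counts={"poorly_adc": (10, 3), "other": (10, 3)})
    return manifest
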