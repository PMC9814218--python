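"""Shared fixtures: synthetic datasets and trained models.

Heavy artifacts (the 30-slide dataset and the two trained classifiers) are
session-scoped so the end-to-end suite pays for generation and training
once.
"""

from __future__ import annotations

import numpy as np
import pytest

from prostriage.synthetic_wsi import generate_dataset
from prostriage.training_engine import TrainingConfig, run_training
from prostriage.wsi_inference import aggregate_wsi, score_slide
from prostriage.wsi_io import SlideImage, read_slide

# study-scale configuration: 128-px tiles over ~1.5-megapixel slides
STUDY_TILE = 128
STUDY_STRIDE = 128
DATASET_SEED = 11
TRAIN_SEED = 5


def study_config(**overrides) -> TrainingConfig:
    base = dict(
        tile_size=STUDY_TILE,
        stride=STUDY_STRIDE,
        draws_per_epoch=8,
        warmup_epochs=2,
        max_epochs=20,
        patience=10,
        seed=TRAIN_SEED,
    )
    base.update(overrides)
    return TrainingConfig(**base)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_slide():
    pixels = np.random.default_rng(7).integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
    return SlideImage(slide_id="small", pixels=pixels)


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    """Balanced 30-slide dataset: 12 train / 6 validation / 12 test."""
    out = tmp_path_factory.mktemp("dataset")
    return generate_dataset(10, out, split_fractions=(0.4, 0.2, 0.4), seed=DATASET_SEED)


@pytest.fixture(scope="session")
def micro_dataset(tmp_path_factory):
    """Tiny 9-slide dataset for fast training-mechanics tests."""
    out = tmp_path_factory.mktemp("micro")
    return generate_dataset(3, out, split_fractions=(0.34, 0.33, 0.33), seed=21,
                            width=768, height=512)


@pytest.fixture(scope="session")
def trained_models(synthetic_dataset):
    """FS+WS- and WS-trained classifiers plus their histories."""
    models = {}
    for mode in ("FS+WS", "WS"):
        models[mode] = run_training(synthetic_dataset, study_config(), mode=mode)
    return models


def predict_split(classifier, manifest, split):
    """Slide predictions and truths for one manifest split."""
    predictions, truths = [], []
    for _, row in manifest.subset(split).iterrows():
        slide = read_slide(row["path"], slide_id=row["slide_id"])
        grid = score_slide(classifier, slide, tile_size=STUDY_TILE, stride=STUDY_STRIDE)
        predictions.append(aggregate_wsi(grid))
        truths.append(row["label"])
    return predictions, truths


@pytest.fixture(scope="session")
def test_predictions(trained_models, synthetic_dataset):
    """Test-split predictions per training mode."""
    out = {}
    for mode, (classifier, _) in trained_models.items():
        out[mode] = predict_split(classifier, synthetic_dataset, "test")
    return out
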