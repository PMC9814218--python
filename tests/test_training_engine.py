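"""Balanced sampling, hard mining, pooling and early stopping."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from prostriage.labeling import pattern_to_class
from prostriage.tile_classifier import TileClassifier, partial_finetune_setup
from prostriage.training_engine import (
    EarlyStopper,
    MiningError,
    SamplingError,
    TrainingConfig,
    mine_hard_tiles,
    run_training,
    sample_balanced_batch,
)
from prostriage.wsi_io import load_annotations

MICRO_CONFIG = dict(
    tile_size=128, stride=128, draws_per_epoch=2, warmup_epochs=1,
    max_epochs=3, patience=2, subset_size=64, batch_size=16,
    tiles_per_wsi_warmup=4,
)


class TestBalancedSampling:
    @pytest.mark.parametrize("mode", ["WS", "FS+WS"])
    def test_batch_draws_three_slides_with_equal_tile_counts(self, micro_dataset, mode):
        config = TrainingConfig(**MICRO_CONFIG, seed=0)
        batch = sample_balanced_batch(micro_dataset, mode, np.random.default_rng(0), config)
        slides, counts = np.unique(batch.source_slide_ids, return_counts=True)
        assert len(slides) == 3
        assert set(counts) == {config.tiles_per_wsi_warmup}
        labels = {s.split("_")[0] for s in slides}
        assert labels == {"benign", "indolent", "aggressive"}

    def test_missing_label_raises_naming_it(self, micro_dataset):
        config = TrainingConfig(**MICRO_CONFIG, seed=0)
        crippled = type(micro_dataset)(
            micro_dataset.table[micro_dataset.table["label"] != "benign"].copy()
        )
        with pytest.raises(SamplingError, match="benign"):
            sample_balanced_batch(crippled, "WS", np.random.default_rng(0), config)

    def test_fs_ws_carcinoma_tiles_centred_in_matching_annotations(self, micro_dataset):
        config = TrainingConfig(**MICRO_CONFIG, seed=0)
        rng = np.random.default_rng(3)
        batch = sample_balanced_batch(micro_dataset, "FS+WS", rng, config)
        ann_by_slide = {}
        for _, row in micro_dataset.subset("train").iterrows():
            if row["annotation_path"]:
                ann_by_slide[row["slide_id"]] = load_annotations(row["annotation_path"])
        # recover tile origin by matching raster content is overkill; instead
        # re-draw with a fresh rng and check centres via the internal helper
        from prostriage.training_engine import _positions_in_annotations, _SlideStore

        store = _SlideStore(micro_dataset, config)
        for _, row in micro_dataset.subset("train").iterrows():
            if row["label"] == "benign" or not row["annotation_path"]:
                continue
            regions = load_annotations(row["annotation_path"])
            positions = store.tissue_positions(row["slide_id"], row["path"])
            allowed = _positions_in_annotations(
                positions, regions, row["label"], config.tile_size
            )
            polys = [
                Polygon(r.vertices)
                for r in regions
                if pattern_to_class(r.pattern) == row["label"]
            ]
            half = config.tile_size / 2
            for x, y in allowed:
                centre = Point(x + half, y + half)
                assert any(p.contains(centre) or p.touches(centre) for p in polys)


class TestHardMining:
    def _classifier(self):
        return TileClassifier("tinyconv", 128, "all", seed=0)

    def test_top_two_of_three_scores(self):
        positions = [(0, 0), (128, 0), (256, 0)]
        scores = np.array([[0.9, 0.1], [0.5, 0.2], [0.1, 0.3]])
        mined = mine_hard_tiles(
            self._classifier(), None, positions, "indolent", 2, tile_size=128, scores=scores
        )
        assert mined == [(0, 0), (128, 0)]

    def test_k_exceeding_grid_returns_all(self):
        positions = [(i * 128, 0) for i in range(5)]
        scores = np.tile([0.5, 0.5], (5, 1))
        mined = mine_hard_tiles(
            self._classifier(), None, positions, "aggressive", 8, tile_size=128, scores=scores
        )
        assert mined == positions

    def test_empty_grid_rejected(self):
        with pytest.raises(MiningError):
            mine_hard_tiles(self._classifier(), None, [], "indolent", 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sort_oracle_with_row_major_tie_break(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 50, 8
        positions = [(int(x) * 64, int(y) * 64) for y in range(5) for x in range(10)]
        # quantized scores force ties so the tie-break rule is exercised
        col = rng.integers(0, 6, size=n) / 5.0
        scores = np.stack([col, rng.random(n)], axis=1)
        mined = mine_hard_tiles(
            self._classifier(), None, positions, "indolent", k, tile_size=64, scores=scores
        )
        # oracle: stable sort by (-score, row-major index), take first k
        order = sorted(range(n), key=lambda i: (-col[i], i))[:k]
        expected = [positions[i] for i in sorted(order)]
        assert mined == expected


class TestEarlyStopping:
    def test_halts_exactly_patience_epochs_after_best(self):
        stopper = EarlyStopper(patience=10)
        losses = [1.0, 0.8, 0.5] + [0.6] * 30  # best at epoch 3, never improves after
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(loss):
                stopped_at = epoch
                break
        assert stopper.best_epoch == 3
        assert stopped_at == 13  # exactly 10 epochs after the best

    def test_improvement_resets_the_clock(self):
        stopper = EarlyStopper(patience=3)
        results = [stopper.update(loss) for loss in [1.0, 0.9, 0.95, 0.95, 0.8, 0.9, 0.9]]
        assert not any(results)  # the epoch-5 improvement reset the counter
        assert stopper.update(0.9)  # third stale epoch after the best -> stop
        assert stopper.best_epoch == 5


class TestRunTraining:
    def test_identical_seed_gives_identical_history(self, micro_dataset):
        histories = []
        for _ in range(2):
            config = TrainingConfig(**MICRO_CONFIG, seed=13)
            _, history = run_training(micro_dataset, config, mode="WS")
            histories.append(history)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].validation_loss == histories[1].validation_loss
        assert histories[0].best_epoch == histories[1].best_epoch

    def test_returns_best_epoch_parameters(self, micro_dataset):
        from prostriage.training_engine import _SlideStore, _wsi_validation_loss

        config = TrainingConfig(**MICRO_CONFIG, seed=13)
        classifier, history = run_training(micro_dataset, config, mode="WS")
        store = _SlideStore(micro_dataset, config)
        val = _wsi_validation_loss(classifier, micro_dataset, config, store)
        assert val == pytest.approx(min(history.validation_loss), abs=1e-9)
        assert history.best_epoch == int(np.argmin(history.validation_loss)) + 1

    def test_stopping_gap_bounded_by_patience(self, micro_dataset):
        config = TrainingConfig(**MICRO_CONFIG, seed=13)
        _, history = run_training(micro_dataset, config, mode="WS")
        assert history.stopped_epoch - history.best_epoch <= config.patience

    def test_pool_consumed_only_in_full_batches(self, micro_dataset):
        config = TrainingConfig(**MICRO_CONFIG, seed=4)
        _, history = run_training(micro_dataset, config, mode="FS+WS")
        for consumed in history.pool_consumed:
            assert consumed % config.batch_size == 0

    def test_partial_policy_keeps_backbone_frozen_across_run(self, micro_dataset):
        config = TrainingConfig(**MICRO_CONFIG, seed=4, trainable_policy="partial")
        reference = TileClassifier("tinyconv", config.tile_size, "partial", seed=config.seed)
        descriptor = partial_finetune_setup(reference)
        frozen = {
            n: v.copy()
            for n, (v, _) in reference.backbone.named_params().items()
            if not descriptor[n]
        }
        classifier, _ = run_training(micro_dataset, config, mode="WS")
        for name, before in frozen.items():
            after = classifier.backbone.named_params()[name][0]
            np.testing.assert_array_equal(after, before)
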