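"""Two-head tile classifier: training contract, masking, policies, persistence."""

import numpy as np
import pytest

from prostriage.tile_classifier import (
    ConfigurationError,
    DegenerateBatchError,
    InputError,
    OptimizerConfig,
    TileBatch,
    TileClassifier,
    load_checkpoint,
    partial_finetune_setup,
    predict_tiles,
    save_checkpoint,
    train_step,
)

SIZE = 32  # smallest input the backbone accepts; keeps these tests fast


def _tiles(n, seed=0, size=SIZE):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 256, size=(n, size, size, 3), dtype=np.uint8)


def _batch(n=8, seed=0, labels=None, mask=None):
    labels = labels if labels is not None else np.tile([1.0, 0.0], (n, 1))
    mask = mask if mask is not None else np.ones((n, 2), dtype=bool)
    return TileBatch(tiles=_tiles(n, seed), labels=labels, mask=mask)


class TestPartialFinetune:
    def test_partial_marks_only_norm_affine_and_head(self):
        clf = TileClassifier("tinyconv", SIZE, "partial", seed=0)
        descriptor = partial_finetune_setup(clf)
        trainable = {n for n, v in descriptor.items() if v}
        assert trainable == {"bn1.gamma", "bn1.beta", "bn2.gamma", "bn2.beta",
                             "head.weight", "head.bias"}

    def test_all_policy_marks_everything(self):
        clf = TileClassifier("tinyconv", SIZE, "all", seed=0)
        assert all(partial_finetune_setup(clf).values())

    def test_trainable_count_below_total_under_partial(self):
        clf = TileClassifier("tinyconv", SIZE, "partial", seed=0)
        descriptor = partial_finetune_setup(clf)
        n_train = sum(clf.backbone.named_params()[n][0].size for n, v in descriptor.items() if v)
        n_total = sum(v.size for v, _ in clf.backbone.named_params().values())
        assert 0 < n_train < n_total

    def test_frozen_parameters_bit_identical_after_step(self):
        clf = TileClassifier("tinyconv", SIZE, "partial", seed=0)
        frozen_before = {
            n: v.copy()
            for n, (v, _) in clf.backbone.named_params().items()
            if not partial_finetune_setup(clf)[n]
        }
        train_step(clf, _batch())
        for name, before in frozen_before.items():
            after = clf.backbone.named_params()[name][0]
            np.testing.assert_array_equal(after, before)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ConfigurationError):
            TileClassifier("tinyconv", SIZE, "frozen", seed=0)


class TestTrainStep:
    def test_uniform_prediction_gives_ln2_loss(self):
        clf = TileClassifier("tinyconv", SIZE, "all", seed=0)
        # zero the head: logits become exactly 0 -> p = 0.5 on both heads
        clf.backbone.head.weight[...] = 0.0
        clf.backbone.head.bias[...] = 0.0
        loss = train_step(clf, _batch())
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_repeated_steps_overfit_fixed_batch(self):
        clf = TileClassifier("tinyconv", SIZE, "all", seed=1)
        batch = _batch(8, seed=3)
        first = train_step(clf, batch)
        last = None
        for _ in range(199):
            last = train_step(clf, batch)
        assert last < first

    def test_masked_pairs_contribute_no_loss(self):
        clf = TileClassifier("tinyconv", SIZE, "all", seed=0)
        labels = np.tile([1.0, 0.0], (4, 1))
        full_mask = np.ones((4, 2), dtype=bool)
        half_mask = full_mask.copy()
        half_mask[:, 1] = False  # aggressive head masked everywhere
        clf.backbone.head.weight[...] = 0.0
        clf.backbone.head.bias[...] = 0.0
        loss = train_step(clf, TileBatch(_tiles(4), labels, half_mask))
        # p = 0.5 against label 1 on the only unmasked head -> exactly ln 2
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_masked_pairs_contribute_no_gradient(self):
        # two classifiers, same seed: one trained with the aggressive head
        # masked, the other with an aggressive label that would move it;
        # masked run must match a run where the head saw nothing at all
        labels_a = np.tile([1.0, 0.0], (4, 1))
        labels_b = np.tile([1.0, 1.0], (4, 1))
        mask = np.ones((4, 2), dtype=bool)
        mask[:, 1] = False
        clf_a = TileClassifier("tinyconv", SIZE, "all", seed=2)
        clf_b = TileClassifier("tinyconv", SIZE, "all", seed=2)
        train_step(clf_a, TileBatch(_tiles(4, 5), labels_a, mask))
        train_step(clf_b, TileBatch(_tiles(4, 5), labels_b, mask))
        for (na, (va, _)), (nb, (vb, _)) in zip(
            clf_a.backbone.named_params().items(), clf_b.backbone.named_params().items()
        ):
            np.testing.assert_array_equal(va, vb), (na, nb)

    def test_all_masked_batch_rejected(self):
        with pytest.raises(DegenerateBatchError):
            TileBatch(_tiles(4), np.zeros((4, 2)), np.zeros((4, 2), dtype=bool))

    def test_training_is_reproducible_run_to_run(self):
        losses = []
        for _ in range(2):
            clf = TileClassifier("tinyconv", SIZE, "all", seed=7)
            run = [train_step(clf, _batch(8, seed=s)) for s in range(5)]
            losses.append(run)
        assert losses[0] == losses[1]


class TestPredict:
    def test_empty_input_empty_output(self):
        clf = TileClassifier("tinyconv", SIZE, "all", seed=0)
        assert predict_tiles(clf, np.zeros((0, SIZE, SIZE, 3), dtype=np.uint8)).shape == (0, 2)

    def test_probabilities_in_unit_interval(self):
        clf = TileClassifier("tinyconv", SIZE, "all", seed=0)
        p = predict_tiles(clf, _tiles(16))
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_duplicated_tile_scores_identically(self):
        clf = TileClassifier("tinyconv", SIZE, "all", seed=0)
        tiles = _tiles(3)
        doubled = np.concatenate([tiles, tiles[:1]])
        p = predict_tiles(clf, doubled)
        np.testing.assert_array_equal(p[0], p[3])

    def test_permutation_equivariance(self):
        clf = TileClassifier("tinyconv", SIZE, "all", seed=0)
        tiles = _tiles(10)
        perm = np.random.default_rng(4).permutation(10)
        np.testing.assert_allclose(
            predict_tiles(clf, tiles[perm]), predict_tiles(clf, tiles)[perm], atol=1e-12
        )

    def test_batched_and_unbatched_calls_agree(self):
        clf = TileClassifier("tinyconv", SIZE, "all", seed=0)
        tiles = _tiles(10)
        np.testing.assert_allclose(
            predict_tiles(clf, tiles, chunk=3), predict_tiles(clf, tiles, chunk=100), atol=1e-12
        )

    def test_size_mismatch_rejected(self):
        clf = TileClassifier("tinyconv", SIZE, "all", seed=0)
        with pytest.raises(InputError):
            predict_tiles(clf, _tiles(2, size=64))

    def test_heads_are_independent_probabilities(self):
        # after pushing both heads positive on a fixed batch, a tile may
        # legitimately score high on both heads at once (no sum-to-one)
        clf = TileClassifier("tinyconv", SIZE, "all", seed=0)
        labels = np.ones((8, 2))
        batch = TileBatch(_tiles(8), labels, np.ones((8, 2), dtype=bool))
        for _ in range(150):
            train_step(clf, batch)
        p = predict_tiles(clf, batch.tiles)
        assert (p.min(axis=1) > 0.7).all()


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        clf = TileClassifier("tinyconv", SIZE, "partial", seed=3)
        train_step(clf, _batch())
        path = save_checkpoint(clf, tmp_path / "model.npz")
        back = load_checkpoint(path)
        assert back.backbone_id == "tinyconv"
        assert back.trainable_policy == "partial"
        tiles = _tiles(5, seed=9)
        np.testing.assert_allclose(predict_tiles(back, tiles), predict_tiles(clf, tiles))
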