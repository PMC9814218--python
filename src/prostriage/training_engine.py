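"""Training orchestration for the two supervision modes.

``WS`` (weak supervision) trains from slide labels alone; ``FS+WS`` starts
from pathologist annotations (full supervision) and then continues exactly
like WS. Both begin with a few warm-up epochs of random balanced tile
sampling — one slide per label per draw, equal tile counts — after which
training alternates between sliding-window inference and hard-example
mining: per sampled slide, the k highest-scoring tiles for the relevant
head(s) enter a training pool, and whenever the pool holds N tiles it is
consumed in batches (leftovers persist; tiles are never silently dropped).

Weak labels for mined tiles: a benign slide supervises both heads negative
(false-positive suppression); an indolent slide supervises the indolent
head positive with the aggressive head masked; an aggressive slide the
converse. The mask keeps legitimate Gleason-3 regions inside aggressive
slides from being pushed toward zero on the indolent head.

Early stopping tracks slide-level validation loss: mean binary
cross-entropy of max-aggregated scores over the unmasked (slide, head)
pairs, with the same masking as the weak labels above. Training halts when
the loss has not improved for ``patience`` epochs and the parameters from
the best epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon

from .labeling import pattern_to_class
from .tile_classifier import (
    OptimizerConfig,
    TileBatch,
    TileClassifier,
    predict_tiles,
    train_step,
)
from .tissue_detection import (
    compute_tissue_mask,
    enumerate_tiles,
    luminance_histogram,
    otsu_threshold,
)
from .wsi_io import (
    SlideImage,
    SlideManifest,
    extract_tile,
    load_annotations,
    read_slide,
)

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "SamplingError",
    "MiningError",
    "EarlyStopper",
    "sample_balanced_batch",
    "mine_hard_tiles",
    "run_training",
]

LABELS = ("benign", "indolent", "aggressive")


class SamplingError(ValueError):
    """Balanced sampling impossible (a label has no training slide)."""


class MiningError(ValueError):
    """Hard mining impossible (empty tile grid)."""


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the mining loop (defaults follow the method)."""

    k: int = 8                     # hard-mined tiles per slide per head
    subset_size: int = 256         # N: pool size consumed per training round
    batch_size: int = 32
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    patience: int = 10             # early-stopping epochs
    warmup_epochs: int = 2         # random-sampling epochs before mining
    tiles_per_wsi_warmup: int = 8
    tile_size: int = 512
    stride: int = 256
    min_tissue_fraction: float = 0.25
    mask_downsample: int = 16
    draws_per_epoch: int = 8       # balanced 3-slide draws per epoch
    max_epochs: int = 50
    backbone_id: str = "tinyconv"
    # "partial" mirrors transfer learning from pretrained weights; training
    # from random initialization (no pretrained backbone ships here) wants "all"
    trainable_policy: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > self.subset_size:
            raise ValueError("need 1 <= k <= subset_size")
        if self.batch_size < 1 or self.batch_size > self.subset_size:
            raise ValueError("need 1 <= batch_size <= subset_size")
        for name in ("patience", "warmup_epochs", "tiles_per_wsi_warmup",
                     "tile_size", "stride", "draws_per_epoch", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def optimizer(self) -> OptimizerConfig:
        return OptimizerConfig(lr=self.lr, beta1=self.beta1, beta2=self.beta2)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    validation_loss: list[float] = field(default_factory=list)
    pool_consumed: list[int] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


class EarlyStopper:
    """Stop when the tracked loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self._epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; returns True when training should stop."""
        self._epoch += 1
        if loss < self.best:
            self.best = loss
            self.best_epoch = self._epoch
        return self._epoch - self.best_epoch >= self.patience

    @property
    def improved(self) -> bool:
        return self.best_epoch == self._epoch


# ---------------------------------------------------------------------------
# slide cache: tissue grids and annotation polygons are reused across epochs


class _SlideStore:
    def __init__(self, manifest: SlideManifest, config: TrainingConfig):
        self.manifest = manifest
        self.config = config
        self._slides: dict[str, SlideImage] = {}
        self._grids: dict[str, list[tuple[int, int]]] = {}
        self._annotations: dict[str, list] = {}

    def slide(self, slide_id: str, path: str) -> SlideImage:
        if slide_id not in self._slides:
            self._slides[slide_id] = read_slide(path, slide_id=slide_id)
        return self._slides[slide_id]

    def tissue_positions(self, slide_id: str, path: str) -> list[tuple[int, int]]:
        if slide_id not in self._grids:
            slide = self.slide(slide_id, path)
            c = self.config
            t = otsu_threshold(luminance_histogram(slide))
            mask = compute_tissue_mask(slide, t, downsample=c.mask_downsample)
            grid = enumerate_tiles(mask, c.tile_size, c.stride, c.min_tissue_fraction)
            self._grids[slide_id] = grid.positions
        return self._grids[slide_id]

    def annotations(self, slide_id: str, ann_path: str | None):
        if slide_id not in self._annotations:
            regions = load_annotations(ann_path, slide_id=slide_id) if ann_path else []
            self._annotations[slide_id] = regions
        return self._annotations[slide_id]


def _weak_labels_for(label: str) -> tuple[tuple[float, float], tuple[bool, bool]]:
    """(labels, mask) per head for tiles drawn from a slide with this label."""
    if label == "benign":
        return (0.0, 0.0), (True, True)
    if label == "indolent":
        return (1.0, 0.0), (True, False)
    if label == "aggressive":
        return (0.0, 1.0), (False, True)
    raise ValueError(f"unknown slide label {label!r}")


def _positions_in_annotations(
    positions: list[tuple[int, int]], regions, klass: str, tile_size: int
) -> list[tuple[int, int]]:
    """Grid positions whose tile centre falls inside a polygon of the class."""
    polys = [Polygon(r.vertices) for r in regions if pattern_to_class(r.pattern) == klass]
    if not polys:
        return []
    half = tile_size / 2.0
    out = []
    for x, y in positions:
        centre = Point(x + half, y + half)
        if any(p.contains(centre) or p.touches(centre) for p in polys):
            out.append((x, y))
    return out


def sample_balanced_batch(
    manifest: SlideManifest,
    mode: str,
    rng: np.random.Generator,
    config: TrainingConfig = TrainingConfig(),
    store: _SlideStore | None = None,
) -> TileBatch:
    """One balanced draw: three slides (one per label), equal tile counts.

    In FS+WS mode carcinoma tiles come only from positions whose centre
    lies inside an annotation polygon of the slide's class; benign tiles
    come from all tissue. In WS mode every label samples from all tissue.
    """
    if mode not in ("WS", "FS+WS"):
        raise ValueError(f"unknown training mode {mode!r}")
    store = store or _SlideStore(manifest, config)
    train = manifest.subset("train")
    tiles, labels, masks, sources = [], [], [], []
    for label in LABELS:
        rows = train[train["label"] == label]
        if rows.empty:
            raise SamplingError(f"no training slide with label {label!r}")
        row = rows.iloc[int(rng.integers(len(rows)))]
        slide = store.slide(row["slide_id"], row["path"])
        positions = store.tissue_positions(row["slide_id"], row["path"])
        if mode == "FS+WS" and label in ("indolent", "aggressive"):
            regions = store.annotations(row["slide_id"], row["annotation_path"])
            if not regions:
                raise SamplingError(
                    f"FS+WS warm-up requires annotations for carcinoma slide {row['slide_id']!r}"
                )
            positions = _positions_in_annotations(positions, regions, label, config.tile_size)
            if not positions:
                raise SamplingError(
                    f"no tissue tile centred in a {label} annotation on {row['slide_id']!r}"
                )
        if not positions:
            raise SamplingError(f"slide {row['slide_id']!r} has no tissue tiles")
        idx = rng.integers(0, len(positions), size=config.tiles_per_wsi_warmup)
        head_labels, head_mask = _weak_labels_for(label)
        for i in idx:
            x, y = positions[int(i)]
            tiles.append(extract_tile(slide, x, y, config.tile_size))
            labels.append(head_labels)
            masks.append(head_mask)
            sources.append(row["slide_id"])
    return TileBatch(
        tiles=np.stack(tiles),
        labels=np.array(labels),
        mask=np.array(masks),
        source_slide_ids=sources,
    )


def mine_hard_tiles(
    classifier: TileClassifier,
    slide: SlideImage,
    positions: list[tuple[int, int]],
    head: str,
    k: int,
    tile_size: int | None = None,
    scores: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """The k grid positions with the highest probability for ``head``.

    Returns all positions when fewer than k exist; ties break toward
    row-major order. Pre-computed ``scores`` (n, 2) skip re-inference when
    mining both heads of one slide.
    """
    if head not in ("indolent", "aggressive"):
        raise ValueError(f"unknown head {head!r}")
    if not positions:
        raise MiningError("cannot mine an empty tile grid")
    if k < 1:
        raise ValueError("k must be >= 1")
    ts = tile_size or classifier.input_size
    if scores is None:
        tiles = np.stack([extract_tile(slide, x, y, ts) for x, y in positions])
        scores = predict_tiles(classifier, tiles)
    col = scores[:, 0] if head == "indolent" else scores[:, 1]
    if len(positions) <= k:
        return list(positions)
    # stable sort on negated scores keeps row-major order among ties
    order = np.argsort(-col, kind="stable")[:k]
    return [positions[int(i)] for i in sorted(order.tolist())]


def _wsi_validation_loss(
    classifier: TileClassifier, manifest: SlideManifest, config: TrainingConfig,
    store: _SlideStore,
) -> float:
    """Mean BCE of max-aggregated slide scores on the validation split.

    Targets mirror the weak-label masking used in training: benign slides
    are negative for both heads, indolent slides positive-indolent and
    negative-aggressive, and aggressive slides positive-aggressive with the
    indolent head masked (aggressive slides legitimately contain Gleason-3
    regions, so a high indolent score there is not an error).
    """
    rows = manifest.subset("validation")
    if rows.empty:
        raise SamplingError("validation split is empty")
    eps = 1e-15
    per_pair: list[float] = []
    for _, row in rows.iterrows():
        slide = store.slide(row["slide_id"], row["path"])
        positions = store.tissue_positions(row["slide_id"], row["path"])
        if not positions:
            continue
        tiles = np.stack([extract_tile(slide, x, y, config.tile_size) for x, y in positions])
        probs = predict_tiles(classifier, tiles)
        score = np.clip(probs.max(axis=0), eps, 1 - eps)  # (p_indolent, p_aggressive)
        y, mask = _weak_labels_for(row["label"])
        for head in range(2):
            if mask[head]:
                p = score[head]
                per_pair.append(float(-(y[head] * np.log(p) + (1 - y[head]) * np.log(1 - p))))
    return float(np.mean(per_pair))


def run_training(
    manifest: SlideManifest,
    config: TrainingConfig = TrainingConfig(),
    mode: str = "FS+WS",
) -> tuple[TileClassifier, TrainingHistory]:
    """Full training loop; returns the best-validation-loss classifier."""
    if mode not in ("WS", "FS+WS"):
        raise ValueError(f"unknown training mode {mode!r}")
    if manifest.subset("train").empty:
        raise SamplingError("training split is empty")
    rng = np.random.default_rng(config.seed)
    classifier = TileClassifier(
        backbone_id=config.backbone_id,
        input_size=config.tile_size,
        trainable_policy=config.trainable_policy,
        seed=config.seed,
    )
    store = _SlideStore(manifest, config)
    opt = config.optimizer()
    stopper = EarlyStopper(config.patience)
    history = TrainingHistory()
    best_state = classifier.state_dict()
    pool: list[tuple[np.ndarray, tuple[float, float], tuple[bool, bool], str]] = []
    train = manifest.subset("train")

    for epoch in range(1, config.max_epochs + 1):
        epoch_losses: list[float] = []
        consumed = 0
        if epoch <= config.warmup_epochs:
            for _ in range(config.draws_per_epoch):
                batch = sample_balanced_batch(manifest, mode, rng, config, store)
                for i in range(len(batch)):
                    pool.append((batch.tiles[i], tuple(batch.labels[i]),
                                 tuple(batch.mask[i]), batch.source_slide_ids[i]))
                consumed += _consume_pool(pool, classifier, config, opt, epoch_losses)
        else:
            for _ in range(config.draws_per_epoch):
                for label in LABELS:
                    rows = train[train["label"] == label]
                    if rows.empty:
                        raise SamplingError(f"no training slide with label {label!r}")
                    row = rows.iloc[int(rng.integers(len(rows)))]
                    slide = store.slide(row["slide_id"], row["path"])
                    positions = store.tissue_positions(row["slide_id"], row["path"])
                    if not positions:
                        continue
                    tiles = np.stack(
                        [extract_tile(slide, x, y, config.tile_size) for x, y in positions]
                    )
                    scores = predict_tiles(classifier, tiles)
                    heads = ("indolent", "aggressive") if label == "benign" else (
                        ("indolent",) if label == "indolent" else ("aggressive",)
                    )
                    head_labels, head_mask = _weak_labels_for(label)
                    for head in heads:
                        mined = mine_hard_tiles(
                            classifier, slide, positions, head, config.k,
                            tile_size=config.tile_size, scores=scores,
                        )
                        for x, y in mined:
                            pool.append(
                                (extract_tile(slide, x, y, config.tile_size),
                                 head_labels, head_mask, row["slide_id"])
                            )
                    if len(pool) >= config.subset_size:
                        consumed += _consume_pool(pool, classifier, config, opt, epoch_losses)
        val_loss = _wsi_validation_loss(classifier, manifest, config, store)
        if not np.isfinite(val_loss):
            raise FloatingPointError("non-finite validation loss")
        history.train_loss.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
        history.validation_loss.append(val_loss)
        history.pool_consumed.append(consumed)
        stop = stopper.update(val_loss)
        if stopper.improved:
            best_state = classifier.state_dict()
        if stop:
            break
    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = len(history.validation_loss)
    classifier.load_state_dict(best_state)
    return classifier, history


def _consume_pool(
    pool: list, classifier: TileClassifier, config: TrainingConfig,
    opt: OptimizerConfig, losses: list[float]
) -> int:
    """Run train steps on full batches from the pool; return tiles consumed."""
    consumed = 0
    while len(pool) >= config.batch_size:
        chunk = pool[: config.batch_size]
        del pool[: config.batch_size]
        batch = TileBatch(
            tiles=np.stack([c[0] for c in chunk]),
            labels=np.array([c[1] for c in chunk]),
            mask=np.array([c[2] for c in chunk]),
            source_slide_ids=[c[3] for c in chunk],
        )
        losses.append(train_step(classifier, batch, opt))
        consumed += len(chunk)
    return consumed
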