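"""Slide-level scoring: sliding-window tile inference, max aggregation,
label-set decision (including double labels) and heatmap rendering.

The slide score for each head is the maximum tile probability over all
tissue tiles; a head whose score reaches the decision threshold enters the
label set. Both heads may fire at once (a double-label slide, typical of
mixed Gleason 3/4 morphology near the 20% boundary); an empty label set
means benign. ``exclusive_label`` collapses the set to a single call by
taking the higher-scoring member, ties going to aggressive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .tile_classifier import TileClassifier, predict_tiles
from .tissue_detection import (
    TileGrid,
    compute_tissue_mask,
    enumerate_tiles,
    luminance_histogram,
    otsu_threshold,
    DEFAULT_MASK_DOWNSAMPLE,
    DEFAULT_MIN_TISSUE_FRACTION,
    DEFAULT_STRIDE,
    DEFAULT_TILE_SIZE,
)
from .wsi_io import SlideImage, extract_tile

__all__ = [
    "TileScoreGrid",
    "WSIPrediction",
    "EmptyTissueError",
    "AggregationError",
    "score_slide",
    "aggregate_wsi",
    "render_heatmap",
]

DEFAULT_DECISION_THRESHOLD = 0.5


class EmptyTissueError(ValueError):
    """Slide contains no tile with enough tissue to score."""


class AggregationError(ValueError):
    """Empty score grid cannot be aggregated to a slide prediction."""


@dataclass
class TileScoreGrid:
    """Per-tile head probabilities aligned with a TileGrid."""

    positions: TileGrid
    p_indolent: np.ndarray
    p_aggressive: np.ndarray
    slide_id: str = ""
    slide_shape: tuple[int, int] | None = None  # (height, width)

    def __post_init__(self) -> None:
        self.p_indolent = np.asarray(self.p_indolent, dtype=np.float64)
        self.p_aggressive = np.asarray(self.p_aggressive, dtype=np.float64)
        n = len(self.positions)
        if self.p_indolent.shape != (n,) or self.p_aggressive.shape != (n,):
            raise ValueError("score arrays must align with tile positions")
        for arr in (self.p_indolent, self.p_aggressive):
            if n and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValueError("tile probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class WSIPrediction:
    """Slide-level scores and label decision."""

    slide_id: str
    score_indolent: float
    score_aggressive: float
    label_set: frozenset[str]
    exclusive_label: str

    @property
    def is_double_label(self) -> bool:
        return self.label_set == frozenset({"indolent", "aggressive"})

    def score(self, head: str) -> float:
        return {"indolent": self.score_indolent, "aggressive": self.score_aggressive}[head]


def score_slide(
    classifier: TileClassifier,
    slide: SlideImage,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int = DEFAULT_STRIDE,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
    mask_downsample: int = DEFAULT_MASK_DOWNSAMPLE,
) -> TileScoreGrid:
    """Score every tissue tile of a slide with the classifier."""
    t = otsu_threshold(luminance_histogram(slide))
    mask = compute_tissue_mask(slide, t, downsample=mask_downsample)
    grid = enumerate_tiles(mask, tile_size, stride, min_tissue_fraction)
    if len(grid) == 0:
        raise EmptyTissueError(f"slide {slide.slide_id!r} has no tissue tile to score")
    tiles = np.stack([extract_tile(slide, x, y, tile_size) for x, y in grid.positions])
    probs = predict_tiles(classifier, tiles)
    return TileScoreGrid(
        positions=grid,
        p_indolent=probs[:, 0],
        p_aggressive=probs[:, 1],
        slide_id=slide.slide_id,
        slide_shape=(slide.height, slide.width),
    )


def aggregate_wsi(grid: TileScoreGrid, threshold: float = DEFAULT_DECISION_THRESHOLD) -> WSIPrediction:
    """Max-aggregate tile scores to a slide prediction.

    A head enters the label set when its max tile probability reaches the
    threshold; the exclusive label is the higher-scoring member of the set
    (ties toward aggressive), or benign when the set is empty.
    """
    if len(grid) == 0:
        raise AggregationError("cannot aggregate an empty score grid")
    if not 0.0 < threshold < 1.0:
        raise ValueError("decision threshold must lie in (0, 1)")
    score_ind = float(grid.p_indolent.max())
    score_agg = float(grid.p_aggressive.max())
    label_set = frozenset(
        label
        for label, score in (("indolent", score_ind), ("aggressive", score_agg))
        if score >= threshold
    )
    if not label_set:
        exclusive = "benign"
    elif label_set == {"indolent"}:
        exclusive = "indolent"
    elif label_set == {"aggressive"}:
        exclusive = "aggressive"
    else:  # double label: pick the larger score, ties toward aggressive
        exclusive = "aggressive" if score_agg >= score_ind else "indolent"
    return WSIPrediction(
        slide_id=grid.slide_id,
        score_indolent=score_ind,
        score_aggressive=score_agg,
        label_set=label_set,
        exclusive_label=exclusive,
    )


def render_heatmap(grid: TileScoreGrid, head: str, slide_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Jet-colormap probability heatmap over the slide footprint.

    Overlapping tiles (stride < tile size) are resolved by per-pixel max,
    consistent with max aggregation; pixels under no tile render at
    probability zero.
    """
    if head not in ("indolent", "aggressive"):
        raise ValueError(f"unknown head {head!r}")
    if len(grid) == 0:
        raise AggregationError("cannot render an empty score grid")
    shape = slide_shape or grid.slide_shape
    if shape is None:
        raise ValueError("slide shape required (pass slide_shape or score via score_slide)")
    h, w = shape
    scores = grid.p_indolent if head == "indolent" else grid.p_aggressive
    canvas = np.zeros((h, w), dtype=np.float64)
    ts = grid.positions.tile_size
    for (x, y), s in zip(grid.positions.positions, scores):
        region = canvas[y : y + ts, x : x + ts]
        np.maximum(region, s, out=region)
    rgba = colormaps["jet"](canvas)
    return (rgba[:, :, :3] * 255).astype(np.uint8)
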