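"""Tissue-vs-background segmentation and tile-grid enumeration.

H&E tissue sits on a near-white scanner background, so a global Otsu
threshold on grayscale luminance separates the two modes; tiles are then
enumerated on a fixed-stride grid restricted to windows with enough tissue.
The mask lives on a downsampled grid (default factor 16) and tile tissue
fractions are measured on that grid, which is an approximation at tile
borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wsi_io import SlideImage

__all__ = [
    "TissueMask",
    "TileGrid",
    "DegenerateHistogramError",
    "luminance",
    "luminance_histogram",
    "otsu_threshold",
    "compute_tissue_mask",
    "enumerate_tiles",
]

DEFAULT_TILE_SIZE = 512
DEFAULT_STRIDE = 256
DEFAULT_MIN_TISSUE_FRACTION = 0.25
DEFAULT_MASK_DOWNSAMPLE = 16


class DegenerateHistogramError(ValueError):
    """Histogram with fewer than two occupied bins cannot be thresholded."""


@dataclass
class TissueMask:
    """Boolean tissue raster at ``downsample``-to-1 scale (True = tissue)."""

    grid: np.ndarray
    downsample: int
    source_slide_id: str
    slide_shape: tuple[int, int]  # (height, width) in slide pixels

    def __post_init__(self) -> None:
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")
        h, w = self.slide_shape
        expect = (-(-h // self.downsample), -(-w // self.downsample))
        if self.grid.shape != expect:
            raise ValueError(f"mask grid {self.grid.shape} != ceil(slide/d) {expect}")


@dataclass
class TileGrid:
    """Row-major sorted, duplicate-free tile positions over one slide."""

    positions: list[tuple[int, int]]
    tile_size: int = DEFAULT_TILE_SIZE
    stride: int = DEFAULT_STRIDE

    def __post_init__(self) -> None:
        self.positions = [(int(x), int(y)) for x, y in self.positions]
        ordered = sorted(set(self.positions), key=lambda p: (p[1], p[0]))
        if ordered != self.positions:
            raise ValueError("tile positions must be row-major sorted and duplicate-free")

    def __len__(self) -> int:
        return len(self.positions)


def luminance(pixels: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma, rounded to the nearest integer in [0, 255]."""
    rgb = pixels.astype(np.float64)
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.rint(y).astype(np.int64)


def luminance_histogram(slide: SlideImage) -> np.ndarray:
    """256-bin count histogram of rounded pixel luminance."""
    return np.bincount(luminance(slide.pixels).ravel(), minlength=256)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Threshold maximizing between-class variance; ties go to the smallest t.

    The split at t puts bins [0..t] in the dark class and [t+1..255] in the
    bright class, so t ranges over [0, 254].
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("need at least two occupied bins for Otsu")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]  # weight of [0..t] for t in 0..254
    w1 = total - w0
    m0 = np.cumsum(hist * levels)[:-1]
    mu0 = np.divide(m0, w0, out=np.zeros_like(m0), where=w0 > 0)
    mu1 = np.divide(hist @ levels - m0, w1, out=np.zeros_like(m0), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(between))  # argmax returns the first (smallest) maximizer


def compute_tissue_mask(slide: SlideImage, t: int, downsample: int = DEFAULT_MASK_DOWNSAMPLE) -> TissueMask:
    """Mark a downsampled cell as tissue iff the majority of its pixels are dark.

    A pixel is dark when its luminance is <= ``t`` (tissue is darker than the
    white background). Border cells are judged on the pixels they actually
    cover.
    """
    if not 0 <= t <= 254:
        raise ValueError(f"threshold must be in [0, 254], got {t}")
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    dark = (luminance(slide.pixels) <= t).astype(np.float64)
    h, w = dark.shape
    gh, gw = -(-h // downsample), -(-w // downsample)
    counts = np.zeros((gh, gw))
    sizes = np.zeros((gh, gw))
    pad_h, pad_w = gh * downsample - h, gw * downsample - w
    dark_p = np.pad(dark, ((0, pad_h), (0, pad_w)))
    cover = np.pad(np.ones_like(dark), ((0, pad_h), (0, pad_w)))
    counts = dark_p.reshape(gh, downsample, gw, downsample).sum(axis=(1, 3))
    sizes = cover.reshape(gh, downsample, gw, downsample).sum(axis=(1, 3))
    grid = counts > sizes / 2.0
    return TissueMask(grid=grid, downsample=downsample, source_slide_id=slide.slide_id,
                      slide_shape=(h, w))


def _axis_weights(start: float, stop: float, n_cells: int, d: int) -> np.ndarray:
    """Length each mask cell's pixel span overlaps [start, stop) along one axis."""
    lo = np.arange(n_cells, dtype=np.float64) * d
    hi = lo + d
    return np.clip(np.minimum(hi, stop) - np.maximum(lo, start), 0.0, None)


def tile_tissue_fraction(mask: TissueMask, x: int, y: int, tile_size: int) -> float:
    """Tissue fraction of the window [x, x+s) x [y, y+s), measured on the mask grid."""
    d = mask.downsample
    gh, gw = mask.grid.shape
    wx = _axis_weights(x, x + tile_size, gw, d)
    wy = _axis_weights(y, y + tile_size, gh, d)
    overlap = wy @ mask.grid.astype(np.float64) @ wx
    return float(overlap / (tile_size * tile_size))


def enumerate_tiles(
    mask: TissueMask,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int = DEFAULT_STRIDE,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
) -> TileGrid:
    """All stride-grid positions fully inside the slide with enough tissue.

    A tile larger than the slide yields an empty grid.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if not 0 < stride <= tile_size:
        raise ValueError("stride must satisfy 0 < stride <= tile_size")
    if not 0.0 <= min_tissue_fraction <= 1.0:
        raise ValueError("min_tissue_fraction must lie in [0, 1]")
    h, w = mask.slide_shape
    d = mask.downsample
    xs = np.arange(0, w - tile_size + 1, stride, dtype=np.int64)
    ys = np.arange(0, h - tile_size + 1, stride, dtype=np.int64)
    if xs.size == 0 or ys.size == 0:
        return TileGrid(positions=[], tile_size=tile_size, stride=stride)
    grid = mask.grid.astype(np.float64)
    gh, gw = grid.shape
    # weight matrices: rows index tile positions, columns mask cells
    wx = np.stack([_axis_weights(x, x + tile_size, gw, d) for x in xs])
    wy = np.stack([_axis_weights(y, y + tile_size, gh, d) for y in ys])
    overlaps = wy @ grid @ wx.T  # (n_y, n_x)
    fractions = overlaps / float(tile_size * tile_size)
    keep = fractions >= min_tissue_fraction - 1e-12
    positions = [(int(xs[j]), int(ys[i])) for i in range(len(ys)) for j in range(len(xs)) if keep[i, j]]
    return TileGrid(positions=positions, tile_size=tile_size, stride=stride)
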