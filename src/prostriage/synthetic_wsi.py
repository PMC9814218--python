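"""Seeded synthetic slides, annotations, manifests and rating matrices.

Slides are desk-scale stand-ins for gigapixel biopsy scans: elongated
rectangular tissue fragments on a pure-white background, painted with three
procedurally generated textures —

* benign: a smooth light-pink field with sparse pale voids,
* GP3-like: a regular small-ring motif (the well-formed-gland look),
* GP4/5-like: a dark, fused, irregular blob field.

The textures are tuned for separability by a small classifier, not for
histological realism. Carcinoma textures are painted in horizontal bands
inside fragments, each band wrapped in a matching rectangular annotation
polygon, so the slide's ground-truth label is derivable from its own
annotations via the 20% area-fraction rule — the generator returns exactly
that derived label. All geometry snaps to a 16-px grid so the Otsu tissue
mask (majority rule at downsample 16) covers fragments exactly.

All randomness flows from the spec seed; identical specs give byte-identical
slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import labeling
from .rater_reliability import CATEGORIES, RatingMatrix
from .wsi_io import (
    AnnotationRegion,
    SlideImage,
    SlideManifest,
    read_manifest,
    save_annotations,
    write_slide,
)

__all__ = [
    "SpecError",
    "SlideSpec",
    "generate_slide",
    "generate_dataset",
    "generate_rating_matrix",
]

GRID = 16  # geometry quantum, matches the default tissue-mask downsample
_MAX_BAND_ROWS = 128
_BAND_GAP = GRID

# texture palette (RGB). All tissue stays strictly darker than the white
# background, and the three classes differ mainly in hue and texture rather
# than raw darkness: the tissue luminance range is kept narrow (roughly
# 110-185) so the global Otsu threshold always falls in the wide gap
# between tissue and the 255-white background instead of splitting dark
# carcinoma from pale benign stroma.
_BENIGN_BASE = (210, 165, 190)
_VOID_COLOR = (226, 206, 218)
_GP3_BASE = (185, 150, 195)
_GP3_RING = (130, 95, 160)
_GP3_LUMEN = (222, 204, 224)
_GP45_BASE = (165, 115, 185)
_GP45_BLOB = (140, 85, 160)


class SpecError(ValueError):
    """Slide spec is internally inconsistent or does not fit the canvas."""


@dataclass
class SlideSpec:
    """Geometry and class-mix recipe for one synthetic slide.

    ``class_mix`` gives target area fractions of the whole slide for the
    benign-tissue, GP3-like and GP4/5-like textures (the remainder is white
    background). When ``gp45_fraction_of_carcinoma`` is set it re-splits the
    carcinoma total so GP4/5 takes exactly that share.
    """

    width: int = 1536
    height: int = 1024
    n_fragments: int = 3
    class_mix: dict = field(
        default_factory=lambda: {"benign_tissue": 0.45, "gp3": 0.0, "gp45": 0.0}
    )
    gp45_fraction_of_carcinoma: float | None = None
    seed: int = 0
    slide_id: str = "synthetic"

    def resolved_mix(self) -> tuple[float, float, float]:
        b = float(self.class_mix.get("benign_tissue", 0.0))
        g3 = float(self.class_mix.get("gp3", 0.0))
        g45 = float(self.class_mix.get("gp45", 0.0))
        if min(b, g3, g45) < 0:
            raise SpecError("class-mix fractions must be non-negative")
        if self.gp45_fraction_of_carcinoma is not None:
            f = self.gp45_fraction_of_carcinoma
            if not 0.0 <= f <= 1.0:
                raise SpecError("gp45_fraction_of_carcinoma must lie in [0, 1]")
            carc = g3 + g45
            g45 = f * carc
            g3 = carc - g45
        total = b + g3 + g45
        if total > 0.90:
            raise SpecError(f"tissue fractions sum to {total:.2f}; need white background")
        return b, g3, g45


def _snap(v: float) -> int:
    return int(round(v / GRID)) * GRID


def _noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    return rng.normal(0.0, sigma, size=shape)


def _paint_benign(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    tex = np.empty((h, w, 3))
    for c in range(3):
        tex[:, :, c] = _BENIGN_BASE[c] + _noise(rng, (h, w), 5.0)
    n_voids = (h * w) // 6000
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_voids):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        r = rng.integers(3, 6)
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        tex[m] = _VOID_COLOR
    return tex


def _paint_gp3(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    tex = np.empty((h, w, 3))
    for c in range(3):
        tex[:, :, c] = _GP3_BASE[c] + _noise(rng, (h, w), 5.0)
    # regular gland motif: rings on a 14-px lattice with a seeded phase
    step = 14
    py, px = int(rng.integers(step)), int(rng.integers(step))
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy + py) % step - step / 2
    dx = (xx + px) % step - step / 2
    r2 = dy * dy + dx * dx
    ring = (r2 >= 9) & (r2 <= 25)
    lumen = r2 < 9
    tex[ring] = _GP3_RING
    tex[lumen] = _GP3_LUMEN
    return tex


def _paint_gp45(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    tex = np.empty((h, w, 3))
    for c in range(3):
        tex[:, :, c] = _GP45_BASE[c] + _noise(rng, (h, w), 8.0)
    # fused irregular blobs: coarse random field upsampled then thresholded
    ch, cw = -(-h // 8), -(-w // 8)
    coarse = rng.normal(size=(ch, cw))
    blob = np.repeat(np.repeat(coarse, 8, axis=0), 8, axis=1)[:h, :w] > 0.3
    tex[blob] = _GP45_BLOB
    return tex


def generate_slide(spec: SlideSpec) -> tuple[SlideImage, list[AnnotationRegion], str]:
    """Compose one synthetic slide; returns (slide, annotations, true label)."""
    b_frac, g3_frac, g45_frac = spec.resolved_mix()
    rng = np.random.default_rng(spec.seed)
    W, H = spec.width, spec.height
    if spec.n_fragments < 1:
        raise SpecError("need at least one fragment")
    tissue_area = (b_frac + g3_frac + g45_frac) * W * H
    frag_h = _snap(0.88 * H)
    frag_y0 = _snap((H - frag_h) / 2)
    frag_w = _snap(tissue_area / (spec.n_fragments * frag_h))
    if frag_w < 4 * GRID:
        raise SpecError("class mix leaves fragments too narrow; raise tissue fractions")
    gap_total = W - spec.n_fragments * frag_w
    if gap_total < (spec.n_fragments + 1) * GRID:
        raise SpecError("fragments do not fit the slide width; lower tissue fractions")
    pitch = gap_total // (spec.n_fragments + 1)
    frag_x = [_snap(pitch * (i + 1) + frag_w * i) for i in range(spec.n_fragments)]

    # --- allocate carcinoma bands inside fragments ------------------------
    def rows_for(area: float) -> int:
        if area <= 0:
            return 0
        return max(GRID, _snap(area / frag_w))

    bands: list[tuple[int, int, int, str]] = []  # (frag index, y, height, pattern group)
    cursor = [frag_y0 + _BAND_GAP] * spec.n_fragments
    order = list(rng.permutation(spec.n_fragments))

    def place(total_rows: int, group: str) -> None:
        remaining = total_rows
        turn = 0
        while remaining > 0:
            h_band = min(remaining, _MAX_BAND_ROWS)
            # pick the fragment with the most free vertical space
            free = [frag_y0 + frag_h - cursor[i] for i in range(spec.n_fragments)]
            i = max(range(spec.n_fragments), key=lambda j: (free[j], -order.index(j)))
            if free[i] < h_band + _BAND_GAP:
                raise SpecError("carcinoma fractions exceed fragment capacity")
            bands.append((i, cursor[i], h_band, group))
            cursor[i] += h_band + _BAND_GAP
            remaining -= h_band
            turn += 1

    place(rows_for(g45_frac * W * H), "gp45")
    place(rows_for(g3_frac * W * H), "gp3")

    # --- paint ------------------------------------------------------------
    canvas = np.full((H, W, 3), 255.0)
    tissue = np.zeros((H, W), dtype=bool)
    for i in range(spec.n_fragments):
        x = frag_x[i]
        canvas[frag_y0 : frag_y0 + frag_h, x : x + frag_w] = _paint_benign(rng, frag_h, frag_w)
        tissue[frag_y0 : frag_y0 + frag_h, x : x + frag_w] = True
    annotations: list[AnnotationRegion] = []
    for i, y, h_band, group in bands:
        x = frag_x[i]
        if group == "gp45":
            tex = _paint_gp45(rng, h_band, frag_w)
            pattern = "GP4" if rng.random() < 0.7 else "GP5"
        else:
            tex = _paint_gp3(rng, h_band, frag_w)
            pattern = "GP3"
        canvas[y : y + h_band, x : x + frag_w] = tex
        annotations.append(
            AnnotationRegion(
                slide_id=spec.slide_id,
                vertices=((x, y), (x + frag_w, y), (x + frag_w, y + h_band), (x, y + h_band)),
                pattern=pattern,
            )
        )
    # tissue channels cap at 250 so the pure-white background (255) stays
    # strictly brighter than every tissue pixel
    canvas[tissue] = np.clip(canvas[tissue], 0, 250)
    pixels = np.rint(canvas).astype(np.uint8)
    slide = SlideImage(slide_id=spec.slide_id, pixels=pixels,
                       microns_per_pixel=0.5, magnification_tag="x20")
    label = labeling.assign_wsi_label(annotations)
    return slide, annotations, label


def _spec_for_label(
    label: str, index: int, width: int, height: int, seed: int, slide_id: str
) -> SlideSpec:
    """Per-label slide recipe with near-boundary GP4/5 fractions mixed in."""
    rng = np.random.default_rng(seed)
    tissue = float(rng.uniform(0.40, 0.55))
    if label == "benign":
        mix = {"benign_tissue": tissue, "gp3": 0.0, "gp45": 0.0}
        gp45 = None
    else:
        carcinoma = float(rng.uniform(0.10, 0.16))
        mix = {"benign_tissue": tissue - carcinoma, "gp3": carcinoma, "gp45": 0.0}
        near_boundary = index % 3 == 2
        if label == "indolent":
            gp45 = float(rng.uniform(0.15, 0.18)) if near_boundary else float(rng.uniform(0.0, 0.12))
        else:
            gp45 = float(rng.uniform(0.21, 0.25)) if near_boundary else float(rng.uniform(0.30, 0.85))
    return SlideSpec(width=width, height=height, class_mix=mix,
                     gp45_fraction_of_carcinoma=gp45, seed=seed, slide_id=slide_id)


def _split_counts(n_per_label: int, split_fractions: Sequence[float]) -> list[int]:
    counts = [int(round(n_per_label * f)) for f in split_fractions]
    counts[0] += n_per_label - sum(counts)  # remainder goes to train
    if min(counts) < 0:
        raise SpecError("split fractions produce a negative count")
    return counts


def generate_dataset(
    n_per_label: int,
    out_dir: str | Path,
    split_fractions: Sequence[float] = (0.4, 0.2, 0.4),
    seed: int = 0,
    width: int = 1536,
    height: int = 1024,
) -> SlideManifest:
    """Write a balanced synthetic dataset (TIFF slides, GeoJSON annotations,
    manifest CSV) and return the loaded manifest.

    Splits follow ``split_fractions`` (train, validation, test) per label;
    indolent slides are drawn with GP4/5 carcinoma fractions below 20% and
    aggressive slides at or above it, including near-boundary cases in the
    0.15-0.25 range so double-label behaviour gets exercised downstream.
    """
    if n_per_label < 1:
        raise SpecError("n_per_label must be >= 1")
    if len(split_fractions) != 3:
        raise SpecError("split_fractions must be (train, validation, test)")
    out_dir = Path(out_dir)
    (out_dir / "slides").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    counts = _split_counts(n_per_label, split_fractions)
    splits = [s for s, c in zip(("train", "validation", "test"), counts) for _ in range(c)]
    rows = []
    for label in ("benign", "indolent", "aggressive"):
        for i in range(n_per_label):
            slide_id = f"{label}_{i:03d}"
            child_seed = int(rng.integers(2**31))
            spec = _spec_for_label(label, i, width, height, child_seed, slide_id)
            slide, annotations, derived = generate_slide(spec)
            if derived != label and label != "benign":
                # band quantization flipped a near-boundary case: nudge the
                # GP4/5 share away from the cutoff and regenerate once
                nudge = -0.04 if label == "indolent" else 0.04
                spec.gp45_fraction_of_carcinoma = min(1.0, max(0.0, spec.gp45_fraction_of_carcinoma + nudge))
                slide, annotations, derived = generate_slide(spec)
            if derived != label:
                raise SpecError(f"could not realise label {label!r} for {slide_id}")
            slide_rel = f"slides/{slide_id}.tiff"
            write_slide(slide, out_dir / slide_rel)
            ann_rel = ""
            if annotations:
                ann_rel = f"annotations/{slide_id}.geojson"
                save_annotations(annotations, out_dir / ann_rel)
            rows.append(
                {"slide_id": slide_id, "path": slide_rel, "label": label,
                 "split": splits[i], "annotation_path": ann_rel}
            )
    table = pd.DataFrame(rows, columns=list(SlideManifest.COLUMNS))
    manifest_path = out_dir / "manifest.csv"
    table.to_csv(manifest_path, index=False)
    return read_manifest(manifest_path)


def generate_rating_matrix(
    n_items: int, n_raters: int, agreement_level: float, seed: int = 0
) -> RatingMatrix:
    """Latent-category rating matrix: each rater reports the item's latent
    category with probability ``agreement_level``, otherwise a uniformly
    chosen other category."""
    if not 0.0 <= agreement_level <= 1.0:
        raise ValueError("agreement_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cats = list(CATEGORIES)
    latent = rng.integers(0, len(cats), size=n_items)
    values = np.empty((n_items, n_raters), dtype=object)
    for i in range(n_items):
        others = [c for c in range(len(cats)) if c != latent[i]]
        for r in range(n_raters):
            if rng.random() < agreement_level:
                values[i, r] = cats[latent[i]]
            else:
                values[i, r] = cats[others[int(rng.integers(len(others)))]]
    frame = pd.DataFrame(
        values,
        index=[f"item{i:04d}" for i in range(n_items)],
        columns=[f"rater{r:02d}" for r in range(n_raters)],
    )
    return RatingMatrix(ratings=frame)
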