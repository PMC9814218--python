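"""Slide, annotation and manifest I/O.

Rasters are plain 8-bit RGB stored as tiled TIFF or PNG; vendor formats
(SVS/JPEG2000) are out of scope here but any reader producing an RGB array
can be adapted to :class:`SlideImage`. Annotations travel as GeoJSON
FeatureCollections whose features carry a ``pattern`` property (GP3/GP4/GP5),
exterior ring only. Manifests are CSV with the header
``slide_id,path,label,split,annotation_path``.

Coordinates are 0-based, origin at the top-left, x rightward, y downward;
tile windows are half-open ``[x, x+size) x [y, y+size)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
from PIL import Image, UnidentifiedImageError
from shapely.geometry import Polygon

__all__ = [
    "GLEASON_PATTERNS",
    "WSI_LABELS",
    "SPLITS",
    "FormatError",
    "AnnotationError",
    "BoundsError",
    "ManifestError",
    "SlideImage",
    "AnnotationRegion",
    "SlideManifest",
    "read_slide",
    "write_slide",
    "extract_tile",
    "load_annotations",
    "save_annotations",
    "read_manifest",
    "write_manifest",
]

GLEASON_PATTERNS = ("GP3", "GP4", "GP5")
WSI_LABELS = ("benign", "indolent", "aggressive")
SPLITS = ("train", "validation", "test")


class FormatError(ValueError):
    """Raised when a file is not in a supported raster format."""


class AnnotationError(ValueError):
    """Raised when an annotation file fails validation."""


class BoundsError(ValueError):
    """Raised when a tile window leaves the slide."""


class ManifestError(ValueError):
    """Raised when a slide manifest fails validation."""


@dataclass
class SlideImage:
    """An RGB slide raster with optional scanner metadata.

    ``pixels`` is a ``(height, width, 3)`` uint8 array. ``microns_per_pixel``
    is metadata only (absent for rasters without resolution tags) and
    ``magnification_tag`` records the nominal objective (e.g. ``"x20"``).
    """

    slide_id: str
    pixels: np.ndarray
    microns_per_pixel: float | None = None
    magnification_tag: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be a (height, width, 3) RGB array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit per channel (uint8)")
        if self.height == 0 or self.width == 0:
            raise ValueError("slide dimensions must be positive")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class AnnotationRegion:
    """A Gleason-pattern polygon on one slide (exterior ring only)."""

    slide_id: str
    vertices: tuple[tuple[float, float], ...]
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in GLEASON_PATTERNS:
            raise AnnotationError(
                f"unknown Gleason pattern {self.pattern!r}; expected one of {GLEASON_PATTERNS}"
            )
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(set(verts)) < 3:
            raise AnnotationError("polygon needs at least 3 distinct vertices")
        poly = Polygon(verts)
        if not poly.is_simple or not poly.is_valid:
            raise AnnotationError("polygon is self-intersecting or otherwise invalid")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class SlideManifest:
    """Slide-level table of paths, labels and splits."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("slide_id", "path", "label", "split", "annotation_path")

    def __post_init__(self) -> None:
        if self.table.empty and not len(self.table.columns):
            self.table = pd.DataFrame(columns=list(self.COLUMNS))
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ManifestError(f"manifest missing columns: {sorted(missing)}")
        if self.table["slide_id"].duplicated().any():
            dupes = self.table.loc[self.table["slide_id"].duplicated(), "slide_id"]
            raise ManifestError(f"duplicate slide_id(s): {sorted(set(dupes))}")
        bad_label = set(self.table["label"]) - set(WSI_LABELS)
        if bad_label:
            raise ManifestError(f"unknown label(s): {sorted(bad_label)}")
        bad_split = set(self.table["split"]) - set(SPLITS)
        if bad_split:
            raise ManifestError(f"unknown split(s): {sorted(bad_split)}")

    def subset(self, split: str) -> pd.DataFrame:
        return self.table[self.table["split"] == split].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def _mpp_from_tiff(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags and "ResolutionUnit" in tags:
        num, den = tags["XResolution"].value
        if num:
            unit = tags["ResolutionUnit"].value  # 2 = inch, 3 = cm
            px_per_unit = num / den
            if px_per_unit > 0:
                unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))
                if unit_um:
                    return unit_um / px_per_unit
    return None


def read_slide(path: str | Path, slide_id: str | None = None) -> SlideImage:
    """Read a tiled TIFF or PNG slide into a :class:`SlideImage`.

    Resolution metadata, when present in the file, is converted to
    microns-per-pixel; PNGs without resolution chunks yield ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such slide file: {path}")
    sid = slide_id or path.stem
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tif:
                arr = tif.asarray()
                mpp = _mpp_from_tiff(tif)
        except (tifffile.TiffFileError, ValueError) as exc:
            raise FormatError(f"not a readable TIFF: {path} ({exc})") from exc
    elif suffix == ".png":
        try:
            with Image.open(path) as img:
                img = img.convert("RGB")
                arr = np.asarray(img)
                dpi = img.info.get("dpi")
        except UnidentifiedImageError as exc:
            raise FormatError(f"not a readable PNG: {path}") from exc
        mpp = 25400.0 / dpi[0] if dpi and dpi[0] else None
    else:
        try:
            with Image.open(path) as img:
                codec = img.format
        except UnidentifiedImageError:
            codec = suffix.lstrip(".") or "unknown"
        raise FormatError(f"unsupported slide codec: {codec} ({path})")
    arr = np.atleast_3d(np.asarray(arr))
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        raise FormatError(f"expected 8-bit RGB, got dtype {arr.dtype} ({path})")
    return SlideImage(slide_id=sid, pixels=arr, microns_per_pixel=mpp)


def write_slide(slide: SlideImage, path: str | Path) -> Path:
    """Write a slide as tiled TIFF or PNG (chosen by extension); lossless."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        kwargs = {}
        if slide.microns_per_pixel:
            px_per_cm = 10000.0 / slide.microns_per_pixel
            kwargs = {"resolution": (px_per_cm, px_per_cm), "resolutionunit": "CENTIMETER"}
        tile = None
        if slide.width >= 256 and slide.height >= 256:
            tile = (256, 256)
        tifffile.imwrite(path, slide.pixels, photometric="rgb", tile=tile, **kwargs)
    elif suffix == ".png":
        Image.fromarray(slide.pixels).save(path)
    else:
        raise FormatError(f"unsupported output format: {suffix}")
    return path


def extract_tile(slide: SlideImage, x: int, y: int, size: int) -> np.ndarray:
    """Return the ``size``-square block with top-left corner at ``(x, y)``."""
    if size <= 0:
        raise BoundsError(f"tile size must be positive, got {size}")
    if x < 0 or y < 0:
        raise BoundsError(f"negative tile origin ({x}, {y})")
    if x + size > slide.width:
        raise BoundsError(f"tile x-window [{x}, {x + size}) exceeds slide width {slide.width}")
    if y + size > slide.height:
        raise BoundsError(f"tile y-window [{y}, {y + size}) exceeds slide height {slide.height}")
    return slide.pixels[y : y + size, x : x + size]


def load_annotations(
    path: str | Path,
    slide_id: str | None = None,
    slide_dims: tuple[int, int] | None = None,
) -> list[AnnotationRegion]:
    """Load Gleason-pattern polygons from a GeoJSON FeatureCollection.

    Every feature must be a Polygon with a ``pattern`` property in
    GP3/GP4/GP5. ``slide_dims`` (width, height), when given, additionally
    checks vertices against the slide bounds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such annotation file: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise AnnotationError(f"expected a GeoJSON FeatureCollection in {path}")
    sid = slide_id or doc.get("slide_id") or path.stem
    regions: list[AnnotationRegion] = []
    for i, feature in enumerate(doc.get("features", [])):
        geom = feature.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise AnnotationError(f"feature {i}: geometry must be Polygon, got {geom.get('type')}")
        rings = geom.get("coordinates") or []
        if not rings:
            raise AnnotationError(f"feature {i}: empty polygon")
        exterior = [(float(x), float(y)) for x, y in rings[0]]
        if len(exterior) > 1 and exterior[0] == exterior[-1]:
            exterior = exterior[:-1]  # GeoJSON closes the ring; we store it open
        pattern = (feature.get("properties") or {}).get("pattern")
        try:
            region = AnnotationRegion(slide_id=sid, vertices=tuple(exterior), pattern=str(pattern))
        except AnnotationError as exc:
            raise AnnotationError(f"feature {i}: {exc}") from exc
        if slide_dims is not None:
            w, h = slide_dims
            for vx, vy in region.vertices:
                if not (0 <= vx <= w and 0 <= vy <= h):
                    raise AnnotationError(
                        f"feature {i}: vertex ({vx}, {vy}) outside slide bounds {w}x{h}"
                    )
        regions.append(region)
    return regions


def save_annotations(regions: Iterable[AnnotationRegion], path: str | Path) -> Path:
    """Write regions as a GeoJSON FeatureCollection (ring closed on output)."""
    regions = list(regions)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = []
    for region in regions:
        ring = [[float(x), float(y)] for x, y in region.vertices]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"pattern": region.pattern},
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if regions:
        doc["slide_id"] = regions[0].slide_id
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


def read_manifest(path: str | Path, resolve_paths: bool = True) -> SlideManifest:
    """Read a slide manifest CSV; relative paths resolve against the CSV's directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    table = table.replace({"annotation_path": {"": None}})
    manifest = SlideManifest(table)
    if resolve_paths:
        base = path.parent

        def _resolve(p):
            if p is None or p == "":
                return p
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        manifest.table["path"] = manifest.table["path"].map(_resolve)
        manifest.table["annotation_path"] = manifest.table["annotation_path"].map(_resolve)
        for _, row in manifest.table.iterrows():
            if not Path(row["path"]).exists():
                raise ManifestError(f"slide path not resolvable: {row['path']}")
            ap = row["annotation_path"]
            if ap and not Path(ap).exists():
                raise ManifestError(f"annotation path not resolvable: {ap}")
    return manifest


def write_manifest(manifest: SlideManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = manifest.table.copy()
    out["annotation_path"] = out["annotation_path"].fillna("")
    out.to_csv(path, index=False)
    return path
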