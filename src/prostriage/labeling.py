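"""Slide labels from Gleason-pattern annotation areas.

A slide with no carcinoma annotations is benign. Otherwise the label
depends on the area fraction of Gleason pattern 4 and 5 within the total
annotated carcinoma area: at least 20% is aggressive (definitive-therapy
candidate), below 20% is indolent (active-surveillance candidate). The
boundary is inclusive: exactly 20% counts as aggressive.

Pattern grouping for tile-level supervision follows the same clinical
reading: GP3 regions supervise the indolent head, GP4 and GP5 regions the
aggressive head.

Overlapping polygons of the same pattern are unioned before measuring area
(free-hand annotations overlap in practice); overlap between different
patterns is counted once per pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from shapely.geometry import Polygon
from shapely.ops import unary_union

from .wsi_io import AnnotationRegion, AnnotationError

__all__ = [
    "AGGRESSIVE_FRACTION_CUTOFF",
    "GleasonAreaSummary",
    "region_area",
    "pattern_to_class",
    "summarize_areas",
    "assign_wsi_label",
]

AGGRESSIVE_FRACTION_CUTOFF = 0.20

_PATTERN_CLASS = {"GP3": "indolent", "GP4": "aggressive", "GP5": "aggressive"}


@dataclass(frozen=True)
class GleasonAreaSummary:
    """Carcinoma area breakdown for one slide, in squared pixels."""

    area_gp3: float
    area_gp45: float

    @property
    def total(self) -> float:
        return self.area_gp3 + self.area_gp45

    @property
    def fraction_gp45(self) -> float | None:
        """GP4+5 share of total carcinoma area; None when no carcinoma."""
        if self.total == 0:
            return None
        return self.area_gp45 / self.total


def region_area(region: AnnotationRegion) -> float:
    """Polygon area by the shoelace formula, winding-independent."""
    poly = Polygon(region.vertices)
    area = poly.area
    if area == 0:
        raise AnnotationError("degenerate polygon with zero area")
    return area


def pattern_to_class(pattern: str) -> str:
    """Map a Gleason pattern to its supervision class (GP3 -> indolent, GP4/5 -> aggressive)."""
    try:
        return _PATTERN_CLASS[pattern]
    except KeyError:
        raise AnnotationError(f"unknown Gleason pattern {pattern!r}") from None


def summarize_areas(regions: Iterable[AnnotationRegion]) -> GleasonAreaSummary:
    """Union same-class polygons, then measure per-class carcinoma area."""
    indolent_polys = []
    aggressive_polys = []
    for region in regions:
        poly = Polygon(region.vertices)
        if pattern_to_class(region.pattern) == "indolent":
            indolent_polys.append(poly)
        else:
            aggressive_polys.append(poly)
    area_gp3 = unary_union(indolent_polys).area if indolent_polys else 0.0
    area_gp45 = unary_union(aggressive_polys).area if aggressive_polys else 0.0
    return GleasonAreaSummary(area_gp3=area_gp3, area_gp45=area_gp45)


def assign_wsi_label(regions: Sequence[AnnotationRegion]) -> str:
    """Slide label from the 20% GP4+5 area-fraction rule (inclusive boundary)."""
    summary = summarize_areas(regions)
    fraction = summary.fraction_gp45
    if fraction is None:
        return "benign"
    if fraction >= AGGRESSIVE_FRACTION_CUTOFF:
        return "aggressive"
    return "indolent"
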