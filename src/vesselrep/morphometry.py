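"""Lumen and wall area from contours or label masks.

Contours are ordered closed polygons in mm; areas are reported in cm^2.  Two
independent paths are provided and cross-checked in the test suite: polygon
integration (shoelace, via shapely) and pixel counting on a rasterized mask.
Rasterization uses the pixel-center convention (pixel (row, col) at
``(y, x) = (row, col) * spacing``, 0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from .exceptions import GeometryError, InsufficientDataError

__all__ = [
    "VesselContours",
    "AreaMeasurement",
    "polygon_area",
    "wall_area",
    "mask_area",
    "circle_polygon",
    "load_contours",
    "save_contours",
]


@dataclass(frozen=True)
class VesselContours:
    """Closed lumen and outer-wall boundary polygons for one slice (mm)."""

    lumen_polygon: tuple[tuple[float, float], ...]
    outer_polygon: tuple[tuple[float, float], ...]
    slice_id: str = ""


@dataclass(frozen=True)
class AreaMeasurement:
    lumen_area_cm2: float
    wall_area_cm2: float


def _as_polygon(vertices) -> Polygon:
    pts = [(float(x), float(y)) for x, y in vertices]
    if len(pts) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    poly = Polygon(pts)
    if not poly.is_simple or not poly.is_valid:
        raise GeometryError("polygon is self-intersecting or otherwise invalid")
    if poly.area == 0:
        raise GeometryError("degenerate (zero-area) polygon")
    return poly


def polygon_area(vertices) -> float:
    """Area of a simple closed polygon given in mm, returned in cm^2.

    Shoelace integration; independent of vertex orientation.
    """
    return _as_polygon(vertices).area / 100.0


def wall_area(contours: VesselContours) -> AreaMeasurement:
    """Lumen area and wall (outer minus lumen) area in cm^2.

    The lumen polygon must lie strictly inside the outer polygon; violations
    (segmentation swaps, crossing contours) raise loudly rather than return a
    signed area.
    """
    lumen = _as_polygon(contours.lumen_polygon)
    outer = _as_polygon(contours.outer_polygon)
    if not outer.contains(lumen):
        raise GeometryError("lumen contour is not strictly inside the outer contour")
    la = lumen.area / 100.0
    wa = (outer.area - lumen.area) / 100.0
    if wa <= 0:
        raise GeometryError("non-positive wall area (degenerate geometry)")
    return AreaMeasurement(lumen_area_cm2=la, wall_area_cm2=wa)


def mask_area(mask: np.ndarray, pixel_spacing_mm: float) -> float:
    """Pixel-counting area of a boolean mask, in cm^2."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise InsufficientDataError("empty mask has no area")
    return n * pixel_spacing_mm**2 / 100.0


def circle_polygon(center_mm, radius_mm: float, n_vertices: int = 360):
    """Regular polygon inscribed in a circle, as contour vertices in mm."""
    if radius_mm <= 0:
        raise GeometryError("radius must be > 0")
    if n_vertices < 3:
        raise GeometryError("need at least 3 vertices")
    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    cx, cy = center_mm
    return tuple(
        (float(cx + radius_mm * np.cos(t)), float(cy + radius_mm * np.sin(t))) for t in theta
    )


def load_contours(path: str | Path) -> VesselContours:
    """Read a contour JSON ``{slice_id, lumen, outer, units: "mm"}``."""
    doc = json.loads(Path(path).read_text())
    if doc.get("units", "mm") != "mm":
        raise GeometryError("contour coordinates must be in mm")
    return VesselContours(
        lumen_polygon=tuple((float(x), float(y)) for x, y in doc["lumen"]),
        outer_polygon=tuple((float(x), float(y)) for x, y in doc["outer"]),
        slice_id=str(doc.get("slice_id", "")),
    )


def save_contours(contours: VesselContours, path: str | Path) -> None:
    doc = {
        "slice_id": contours.slice_id,
        "lumen": [list(p) for p in contours.lumen_polygon],
        "outer": [list(p) for p in contours.outer_polygon],
        "units": "mm",
    }
    Path(path).write_text(json.dumps(doc, indent=1))
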