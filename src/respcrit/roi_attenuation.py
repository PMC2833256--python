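"""Mean attenuation and area of a polygonal ROI on a 2-D CT-like slice.

This is the measurement primitive behind attenuation-based response criteria:
a radiologist draws a perimeter around a lesion on one axial slice and the
viewer reports the enclosed area and the mean Hounsfield value of the pixels
inside it.

Conventions (documented to avoid half-pixel drift):

* Coordinates are continuous millimetres with the origin at the **centre** of
  pixel (row 0, col 0); x runs along columns, y along rows.
* A pixel belongs to the ROI when its centre lies inside the polygon; points
  exactly on an edge count as inside.
* Display windowing never affects measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely

from .survival_stats import spearman_corr

__all__ = [
    "SliceImage",
    "PolygonROI",
    "mean_attenuation_in_roi",
    "intra_observer_agreement",
    "save_slice_png",
    "load_slice_png",
    "save_roi_json",
    "load_roi_json",
]


@dataclass(frozen=True)
class SliceImage:
    """A 2-D grid of attenuation values (HU) with physical pixel spacing."""

    pixel_values: np.ndarray  # shape (rows, cols), HU
    pixel_spacing_mm: tuple[float, float]  # (row, col)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixel_values, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("pixel_values must be a non-empty 2-D grid")
        object.__setattr__(self, "pixel_values", arr)
        dr, dc = self.pixel_spacing_mm
        if dr <= 0 or dc <= 0:
            raise ValueError("pixel spacing must be strictly positive")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1]


@dataclass(frozen=True)
class PolygonROI:
    """Ordered polygon vertices in mm, image coordinate frame, implicitly closed."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)
        poly = shapely.Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            raise ValueError("degenerate or self-intersecting polygon")

    def as_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def translated(self, dx: float, dy: float) -> "PolygonROI":
        return PolygonROI(tuple((x + dx, y + dy) for x, y in self.vertices))


def mean_attenuation_in_roi(
    image: SliceImage, roi: PolygonROI
) -> tuple[float, float, int]:
    """Mean HU, area (mm^2) and pixel count of the ROI on ``image``.

    The mean is taken over pixels whose centres fall inside (or on the edge
    of) the polygon; the area is that pixel count times the pixel area.

    Raises
    ------
    ValueError
        If no pixel centre falls inside the polygon ("empty ROI").
    """
    rows, cols = image.pixel_values.shape
    dr, dc = image.pixel_spacing_mm
    poly = roi.as_shapely()

    # restrict the centre grid to the polygon's bounding box
    minx, miny, maxx, maxy = poly.bounds
    c_lo = max(0, int(np.ceil(minx / dc - 1e-12)))
    c_hi = min(cols - 1, int(np.floor(maxx / dc + 1e-12)))
    r_lo = max(0, int(np.ceil(miny / dr - 1e-12)))
    r_hi = min(rows - 1, int(np.floor(maxy / dr + 1e-12)))
    if c_lo > c_hi or r_lo > r_hi:
        raise ValueError("empty ROI: polygon does not cover any pixel centre")

    rr, cc = np.meshgrid(
        np.arange(r_lo, r_hi + 1), np.arange(c_lo, c_hi + 1), indexing="ij"
    )
    xs = cc.ravel() * dc
    ys = rr.ravel() * dr
    # boundary-inclusive membership: a centre on the perimeter counts as inside
    inside = shapely.intersects_xy(poly, xs, ys)
    n_pixels = int(inside.sum())
    if n_pixels == 0:
        raise ValueError("empty ROI: polygon does not cover any pixel centre")

    values = image.pixel_values[rr.ravel()[inside], cc.ravel()[inside]]
    mean_hu = float(values.mean())
    area_mm2 = n_pixels * image.pixel_area_mm2
    return mean_hu, area_mm2, n_pixels


def intra_observer_agreement(
    measurements_day1: Sequence[tuple[str, float]],
    measurements_day2: Sequence[tuple[str, float]],
) -> float:
    """Spearman rank correlation between repeated HU measurements.

    Quantifies intra-observer reproducibility of ROI placement: the same
    observer re-measures the same lesions on a different day and the two HU
    series are rank-correlated.
    """
    d1 = dict(measurements_day1)
    d2 = dict(measurements_day2)
    if len(d1) != len(measurements_day1) or len(d2) != len(measurements_day2):
        raise ValueError("duplicate lesion_id in a measurement list")
    if set(d1) != set(d2):
        raise ValueError("lesion_id sets differ between the two sessions")
    if len(d1) < 3:
        raise ValueError("need at least 3 lesions for a rank correlation")
    ids = sorted(d1)
    rho, _ = spearman_corr([d1[i] for i in ids], [d2[i] for i in ids])
    return rho


# ---------------------------------------------------------------------------
# Fixture I/O: 16-bit grayscale PNG + JSON sidecar; GeoJSON-style polygons
# ---------------------------------------------------------------------------

def save_slice_png(image: SliceImage, png_path: str | Path) -> None:
    """Write a slice as 16-bit grayscale PNG with a JSON sidecar.

    The sidecar records the affine HU = scale * stored + offset and the pixel
    spacing, so HU values round-trip exactly for integer-valued grids.
    """
    from PIL import Image

    png_path = Path(png_path)
    arr = image.pixel_values
    lo = float(arr.min())
    hi = float(arr.max())
    # scale 1 whenever the range fits 16 bits: integer HU round-trip exactly
    scale = 1.0 if hi - lo <= 65535.0 else (hi - lo) / 65535.0
    stored = np.round((arr - lo) / scale).astype(np.uint16)
    Image.fromarray(stored).save(png_path)
    sidecar = {
        "hu_offset": lo,
        "hu_scale": scale,
        "pixel_spacing_mm": list(image.pixel_spacing_mm),
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_slice_png(png_path: str | Path) -> SliceImage:
    from PIL import Image

    png_path = Path(png_path)
    meta = json.loads(png_path.with_suffix(".json").read_text())
    stored = np.asarray(Image.open(png_path), dtype=float)
    hu = stored * meta["hu_scale"] + meta["hu_offset"]
    return SliceImage(hu, tuple(meta["pixel_spacing_mm"]))


def save_roi_json(roi: PolygonROI, path: str | Path) -> None:
    geo = {"type": "Polygon", "coordinates": [[list(v) for v in roi.vertices]]}
    Path(path).write_text(json.dumps(geo, indent=2))


def load_roi_json(path: str | Path) -> PolygonROI:
    geo = json.loads(Path(path).read_text())
    if geo.get("type") != "Polygon":
        raise ValueError("expected a GeoJSON-style Polygon")
    ring = geo["coordinates"][0]
    # GeoJSON rings repeat the first vertex; our polygons close implicitly
    if len(ring) > 3 and ring[0] == ring[-1]:
        ring = ring[:-1]
    return PolygonROI(tuple((x, y) for x, y in ring))
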