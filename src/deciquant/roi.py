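"""Regions of disinterest and tissue-area measurement.

The decidua contains structures that must not contribute to protein
quantification — muscle, villous placental tissue, blood vessels,
endometrial glands and areas of poor morphology.  These are supplied as
manually drawn polygons; this module rasterizes them, combines them with a
brightness-based tissue mask, and reports the included tissue area in mm².

Coordinate convention (project-wide): 0-based pixels, origin top-left,
half-open intervals.  Polygon vertices are stored as (x, y) = (column, row)
pairs, the convention of common annotation tools and of well-known
geometry text (WKT) serializations; rasters are row-major (y first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely import wkt as shapely_wkt
from shapely.geometry import Polygon, box
from skimage.draw import polygon2mask
from skimage.morphology import remove_small_holes, remove_small_objects

from deciquant.stitching import SlideScan

__all__ = ["ROIMask", "tissue_mask", "apply_roi", "read_roi", "write_roi"]

ROI_LABELS = ("muscle", "villous", "vessel", "gland", "poor_morphology", "other")


@dataclass
class ROIMask:
    """Labeled exclusion polygons in scan pixel coordinates."""

    polygons: list[tuple[str, Polygon]] = field(default_factory=list)

    def __post_init__(self) -> None:
        checked = []
        for label, poly in self.polygons:
            if not isinstance(poly, Polygon):
                poly = Polygon(poly)
            if not poly.is_valid:
                poly = poly.buffer(0)  # heal minor self-intersections
            if poly.is_empty or not poly.is_valid:
                raise ValueError(f"polygon labeled {label!r} is invalid")
            checked.append((label, poly))
        self.polygons = checked

    @classmethod
    def from_vertices(cls, items: list[tuple[str, np.ndarray]]) -> "ROIMask":
        """Build from (label, (n, 2) array of (x, y) vertices) pairs."""
        return cls([(label, Polygon(np.asarray(v, dtype=float))) for label, v in items])

    def raster(self, shape: tuple[int, int]) -> np.ndarray:
        """Union of all polygons as a boolean raster of the given shape.

        Polygons extending outside the canvas are clipped with a warning.
        """
        h, w = shape
        canvas = box(0, 0, w, h)
        mask = np.zeros(shape, dtype=bool)
        for label, poly in self.polygons:
            if not canvas.contains(poly):
                warnings.warn(
                    f"polygon labeled {label!r} extends outside the canvas; clipped",
                    stacklevel=2,
                )
            # polygon2mask wants (row, col) points
            pts = np.asarray(poly.exterior.coords)[:, ::-1]
            mask |= polygon2mask(shape, pts)
        return mask


def tissue_mask(
    scan: SlideScan,
    white_threshold: float = 230.0,
    smooth_sigma: float = 0.0,
    min_speck_px: int = 64,
) -> np.ndarray:
    """Brightness-based tissue detection.

    A pixel is tissue iff its smoothed luma is below ``white_threshold``;
    small holes (below ``min_speck_px``) are filled — larger unstained
    lakes such as fibrinoid stay background — and connected specks smaller
    than ``min_speck_px`` are removed.  With ``white_threshold`` 255 every
    pixel is tissue.
    """
    gray = scan.gray()
    if smooth_sigma > 0:
        gray = gaussian_filter(gray, sigma=smooth_sigma)
    mask = gray < white_threshold
    if white_threshold >= 255.0:
        # degenerate threshold: smoothing rounds nothing out of range
        return np.ones_like(mask, dtype=bool)
    if mask.any():
        mask = remove_small_holes(mask, max_size=min_speck_px - 1)
        mask = remove_small_objects(mask, max_size=min_speck_px - 1)
    return mask


def apply_roi(
    tissue: np.ndarray, roi: ROIMask, pixel_size: float
) -> tuple[np.ndarray, float]:
    """Remove regions of disinterest and measure the remaining tissue area.

    ``included = tissue AND NOT any polygon``;
    ``area_mm2 = included pixel count × (pixel_size/1000)²``.  The area
    denominator counts tissue pixels only, not the bounding rectangle.
    """
    excl = roi.raster(tissue.shape)
    included = tissue & ~excl
    area_mm2 = float(included.sum()) * (pixel_size / 1000.0) ** 2
    return included, area_mm2


def write_roi(roi: ROIMask, path) -> None:
    """Write polygons as a delimited text table: label, WKT geometry."""
    pd.DataFrame(
        [(label, poly.wkt) for label, poly in roi.polygons],
        columns=["label", "wkt"],
    ).to_csv(path, index=False)


def read_roi(path) -> ROIMask:
    df = pd.read_csv(path)
    return ROIMask(
        [(row.label, shapely_wkt.loads(row.wkt)) for row in df.itertuples()]
    )
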