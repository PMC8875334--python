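"""Flat-field correction and tile stitching of bright-field scans.

Slide scanners acquire a grid of partially overlapping tiles whose
illumination falls off smoothly toward the tile edges (vignetting).  Because
the shading originates in the optics it is common to every tile of a scan
and multiplicative in intensity, so it is estimated once per tile set and
divided out before the tiles are assembled into a single mosaic.

Tile positions come from the declared grid layout (scanner stages report
positions); no correlation-based placement is attempted, which keeps
stitching deterministic.  Overlaps are blended by linear feathering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from deciquant.phantom import TileSet

__all__ = [
    "SlideScan",
    "FlatField",
    "estimate_flatfield",
    "correct_tiles",
    "stitch",
    "cut_into_tiles",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class SlideScan:
    """A stitched 8-bit RGB section scan with calibration and provenance."""

    image: np.ndarray  # uint8, (H, W, 3)
    pixel_size: float  # µm/px
    marker: str
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    def gray(self) -> np.ndarray:
        """Rec. 601 luma in [0, 255] (float)."""
        return self.image.astype(float) @ _LUMA


@dataclass
class FlatField:
    """Smooth per-channel multiplicative gain raster of tile shape.

    Strictly positive everywhere; each channel is normalized to mean gain 1.
    """

    field: np.ndarray  # float, (h, w, 3)

    def __post_init__(self) -> None:
        if np.any(self.field <= 0):
            raise ValueError("flat-field gain must be strictly positive")

    @classmethod
    def identity(cls, tile_shape: tuple[int, int]) -> "FlatField":
        return cls(np.ones(tile_shape + (3,), dtype=float))


def _poly2_fit(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Least-squares 2-D quadratic surface through ``values[mask]``."""
    h, w = values.shape
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy / max(h - 1, 1)).ravel()
    x = (xx / max(w - 1, 1)).ravel()
    design = np.column_stack([np.ones_like(x), x, y, x * x, y * y, x * y])
    m = mask.ravel()
    coef, *_ = np.linalg.lstsq(design[m], values.ravel()[m], rcond=None)
    return (design @ coef).reshape(h, w)


def estimate_flatfield(
    tiles: TileSet,
    background_luma_min: float = 150.0,
    min_background_fraction: float = 0.005,
) -> FlatField:
    """Estimate the shared shading field from a tile set's background.

    Per channel, the per-pixel median over the background-classified pixels
    of all tiles (luma above ``background_luma_min``) is taken, a smooth
    quadratic surface is fitted through it (the low-pass step), and the
    surface is normalized to mean gain 1.  If less than
    ``min_background_fraction`` of all pixels classify as background the
    field is not estimable; an identity field is returned with a warning.
    """
    if not tiles.tiles:
        raise ValueError("at least one tile is required")
    stack = np.stack([t for t in tiles.tiles]).astype(np.float32)  # (n, h, w, 3)
    luma = stack @ _LUMA.astype(np.float32)
    bg = luma > background_luma_min  # (n, h, w)
    if bg.mean() < min_background_fraction:
        warnings.warn(
            "tiles contain almost no background; returning identity flat field",
            stacklevel=2,
        )
        return FlatField.identity(tiles.tile_shape)

    h, w = tiles.tile_shape
    gain = np.ones((h, w, 3), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixel columns
        for ch in range(3):
            vals = np.where(bg, stack[..., ch], np.nan)
            med = np.nanmedian(vals, axis=0)
            have = np.isfinite(med)
            if have.mean() < min_background_fraction:
                continue
            surface = _poly2_fit(med, have)
            surface = np.clip(surface, 1e-3, None)
            gain[..., ch] = surface / surface.mean()
    return FlatField(np.clip(gain, 0.05, None))


def correct_tiles(tiles: TileSet, flat: FlatField) -> TileSet:
    """Divide each tile by the gain field, preserving global mean brightness.

    The per-channel mean over all tiles is restored after division so that
    correction changes shading, not exposure; output is clipped to 8 bit.
    """
    if flat.field.shape[:2] != tiles.tile_shape:
        raise ValueError(
            f"flat field shape {flat.field.shape[:2]} != tile shape {tiles.tile_shape}"
        )
    stack = np.stack([t for t in tiles.tiles]).astype(np.float32)
    before = stack.mean(axis=(0, 1, 2), dtype=np.float64)
    corrected = stack / flat.field[None].astype(np.float32)
    after = corrected.mean(axis=(0, 1, 2), dtype=np.float64)
    scale = np.where(after > 0, before / np.maximum(after, 1e-9), 1.0)
    corrected *= scale[None, None, None, :].astype(np.float32)
    np.rint(corrected, out=corrected)
    np.clip(corrected, 0, 255, out=corrected)
    return TileSet(
        tiles=[t.astype(np.uint8) for t in corrected],
        grid_layout=tiles.grid_layout,
        overlap=tiles.overlap,
        pixel_size=tiles.pixel_size,
        marker=tiles.marker,
    )


def _feather_weights(n: int, overlap: int, length: int) -> list[np.ndarray]:
    """Per-tile 1-D blending weights along one axis of the grid."""
    ramps = []
    ramp_up = (np.arange(1, overlap + 1)) / (overlap + 1) if overlap else np.empty(0)
    for i in range(n):
        wgt = np.ones(length)
        if overlap:
            if i > 0:
                wgt[:overlap] = ramp_up
            if i < n - 1:
                wgt[-overlap:] = ramp_up[::-1]
        ramps.append(wgt)
    return ramps


def stitch(tiles: TileSet) -> SlideScan:
    """Assemble a tile grid into a single scan.

    Tiles are placed at their declared grid positions; overlap regions are
    blended with linear feathering.  At zero overlap the mosaic is the exact
    concatenation of the tiles.  A missing tile (``None``) raises an error
    naming its grid position.
    """
    rows, cols = tiles.grid_layout
    missing = [
        (i // cols, i % cols) for i, t in enumerate(tiles.tiles) if t is None
    ]
    if missing:
        raise ValueError(f"missing tiles at grid positions {missing}")
    th, tw = tiles.tile_shape
    ov = tiles.overlap
    full_h = rows * (th - ov) + ov
    full_w = cols * (tw - ov) + ov
    if ov == 0:  # exact concatenation, no blending arithmetic
        image = np.empty((full_h, full_w, 3), dtype=np.uint8)
        for r in range(rows):
            for c in range(cols):
                image[r * th : (r + 1) * th, c * tw : (c + 1) * tw] = tiles.tile_at(r, c)
        return SlideScan(
            image=image,
            pixel_size=tiles.pixel_size,
            marker=tiles.marker,
            provenance={"grid_layout": (rows, cols), "overlap": 0, "blend": "none"},
        )
    acc = np.zeros((full_h, full_w, 3), dtype=float)
    wsum = np.zeros((full_h, full_w), dtype=float)
    row_w = _feather_weights(rows, ov, th)
    col_w = _feather_weights(cols, ov, tw)
    for r in range(rows):
        for c in range(cols):
            tile = tiles.tile_at(r, c).astype(float)
            wgt = np.outer(row_w[r], col_w[c])
            y0 = r * (th - ov)
            x0 = c * (tw - ov)
            acc[y0 : y0 + th, x0 : x0 + tw] += tile * wgt[..., None]
            wsum[y0 : y0 + th, x0 : x0 + tw] += wgt
    image = acc / np.maximum(wsum, 1e-12)[..., None]
    return SlideScan(
        image=np.clip(np.rint(image), 0, 255).astype(np.uint8),
        pixel_size=tiles.pixel_size,
        marker=tiles.marker,
        provenance={"grid_layout": (rows, cols), "overlap": ov, "blend": "linear-feather"},
    )


def cut_into_tiles(
    scan: SlideScan, tile_shape: tuple[int, int], overlap: int = 0
) -> TileSet:
    """Cut a scan into a tile grid (inverse of :func:`stitch` for testing
    and for re-tiling externally produced mosaics).  The scan is padded with
    white to an exact grid if needed."""
    from deciquant.phantom import tiling_layout

    rows, cols = tiling_layout(scan.shape, tile_shape, overlap)
    th, tw = tile_shape
    full_h = rows * (th - overlap) + overlap
    full_w = cols * (tw - overlap) + overlap
    padded = np.full((full_h, full_w, 3), 255, dtype=np.uint8)
    padded[: scan.shape[0], : scan.shape[1]] = scan.image
    out = []
    for r in range(rows):
        for c in range(cols):
            y0 = r * (th - overlap)
            x0 = c * (tw - overlap)
            out.append(padded[y0 : y0 + th, x0 : x0 + tw].copy())
    return TileSet(
        tiles=out,
        grid_layout=(rows, cols),
        overlap=overlap,
        pixel_size=scan.pixel_size,
        marker=scan.marker,
    )
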