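"""Synthetic serial-section IHC slide phantoms with ground truth.

A :class:`SlidePhantom` describes one block of decidual tissue: a smooth
stromal occupancy field (maternal tissue), disk-shaped extravillous
trophoblast cells placed either in interstitial clusters or as single cells,
and polygonal exclusion structures (vessels, glands).  Three "serial
sections" of the block — the CK7 reference section and the NRF2 and KEAP1
marker sections — share the spatial layout but differ in DAB stain strength
and carry a small rigid offset, mimicking parallel 3 µm sections scanned on
the same stage.

Rendering follows a two-stain Lambert-Beer model: per-pixel hematoxylin and
DAB optical densities are mixed through the reference absorbance vectors of
the H-DAB color model and exponentiated onto a white background, so the
deconvolution stage in :mod:`deciquant.quant` can invert the model exactly.
Rendered gray level is therefore strictly decreasing in stain strength at
zero noise (the inverse-intensity convention: darker means more protein).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter
from skimage.color import rgb_from_hdx
from skimage.draw import polygon2mask

__all__ = [
    "SlidePhantom",
    "TileSet",
    "PackingError",
    "SINGLE_CELL_ID",
    "generate_phantom",
    "render_canvas",
    "render_section",
    "phantom_patch_truth",
    "rasterize_cells",
    "exclusion_raster",
]

#: cluster_id used for trophoblasts placed as single cells
SINGLE_CELL_ID = 0

# Hematoxylin OD applied to stroma at full occupancy / to trophoblast
# cells / to the confluent cluster cytoplasm between cells.
_HEMA_STROMA = 0.45
_HEMA_CELL = 0.65
_HEMA_CARPET = 0.50
# DAB strength of the confluent cytoplasm relative to the cells
_CARPET_DAB = 0.9

_DEFAULT_MARKER_STRENGTHS = {
    # marker -> (trophoblast DAB strength, maternal DAB strength), in [0, 1]
    "CK7": (0.90, 0.02),
    "NRF2": (0.65, 0.15),
    "KEAP1": (0.60, 0.12),
}


class PackingError(ValueError):
    """Requested cell layout cannot be placed on the canvas."""


@dataclass
class SlidePhantom:
    """Ground-truth layout of one synthetic decidual tissue block.

    Attributes
    ----------
    canvas_size : (height, width) in pixels.
    pixel_size : physical pixel size in µm/px.
    trophoblast_cells : array of shape (n, 4): (cy, cx, radius, cluster_id).
        ``cluster_id`` is 1..n_clusters for clustered cells and
        ``SINGLE_CELL_ID`` (0) for single cells.
    stroma_field : float map in [0, 1]; maternal tissue occupancy.
    exclusion_regions : list of (label, vertices) with vertices an (m, 2)
        array of (row, col) canvas coordinates forming a closed polygon.
    marker_strengths : marker -> (trophoblast DAB, maternal DAB) in [0, 1].
    section_offsets : marker -> (dy, dx) rigid translation in px applied to
        that section's content relative to the block layout.
    seed : the generator seed; regeneration with the same arguments and
        seed reproduces the phantom bit-identically.
    """

    canvas_size: tuple[int, int]
    pixel_size: float
    trophoblast_cells: np.ndarray
    stroma_field: np.ndarray
    exclusion_regions: list[tuple[str, np.ndarray]]
    marker_strengths: dict[str, tuple[float, float]]
    section_offsets: dict[str, tuple[int, int]]
    seed: int
    clusters: np.ndarray = None  # (n_clusters, 3): cy, cx, radius
    cluster_style: str = "confluent"

    def __post_init__(self) -> None:
        if self.clusters is None:
            self.clusters = np.empty((0, 3), dtype=float)

    @property
    def n_cells(self) -> int:
        return int(self.trophoblast_cells.shape[0])

    def carpet_raster(self) -> np.ndarray:
        """Confluent cytoplasmic carpet of the interstitial clusters.

        In the confluent style the space between clustered cells is filled
        by CK7-positive trophoblast cytoplasm; in the discrete style there
        is no carpet.
        """
        h, w = self.canvas_size
        if self.cluster_style != "confluent" or self.clusters.shape[0] == 0:
            return np.zeros((h, w), dtype=bool)
        mask = np.zeros((h, w), dtype=bool)
        for cy, cx, r in self.clusters:
            y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
            x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        return mask

    def trophoblast_raster(self) -> np.ndarray:
        """True trophoblast pixels: cell disks plus the confluent carpet."""
        return rasterize_cells(self) | self.carpet_raster()

    def tissue_truth(self) -> np.ndarray:
        """True tissue mask: stroma, trophoblast pixels, and the excluded
        structures (vessels/glands are stained tissue too); the fibrinoid
        surrounding the clusters is unstained and counts as background."""
        return (
            (self.stroma_field > 0)
            | self.trophoblast_raster()
            | exclusion_raster(self.canvas_size, self.exclusion_regions)
        )


@dataclass
class TileSet:
    """Grid of bright-field RGB tiles from one section scan.

    ``tiles`` is a row-major list of uint8 arrays of identical shape
    ``tile_shape + (3,)``; ``grid_layout`` is (rows, cols); adjacent tiles
    share ``overlap`` pixels along the common edge.
    """

    tiles: list[np.ndarray]
    grid_layout: tuple[int, int]
    overlap: int
    pixel_size: float
    marker: str

    def __post_init__(self) -> None:
        rows, cols = self.grid_layout
        if rows * cols != len(self.tiles):
            raise ValueError(
                f"grid_layout {self.grid_layout} does not match {len(self.tiles)} tiles"
            )
        shapes = {t.shape for t in self.tiles if t is not None}
        if len(shapes) > 1:
            raise ValueError(f"tiles have inconsistent shapes: {shapes}")

    @property
    def tile_shape(self) -> tuple[int, int]:
        first = next(t for t in self.tiles if t is not None)
        return first.shape[:2]

    def tile_at(self, row: int, col: int) -> np.ndarray | None:
        return self.tiles[row * self.grid_layout[1] + col]


def _place_points(
    rng: np.random.Generator,
    n: int,
    low: np.ndarray,
    high: np.ndarray,
    min_dist: float,
    anchors: list[tuple[np.ndarray, float]] | None = None,
    max_tries: int = 4000,
) -> list[np.ndarray]:
    """Rejection-sample n points in a box with pairwise minimum distance.

    ``anchors`` are (point, keep-out radius) pairs for previously placed
    structures of possibly different sizes.
    """
    pts: list[np.ndarray] = []
    anchors = anchors or []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {n} objects with separation {min_dist:.1f} px "
                f"in box {tuple(low)}..{tuple(high)}"
            )
        cand = rng.uniform(low, high)
        ok = all(np.hypot(*(cand - p)) >= min_dist for p in pts) and all(
            np.hypot(*(cand - p)) >= d for p, d in anchors
        )
        if ok:
            pts.append(cand)
        tries += 1
    return pts


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, int], rel_sigma: float, factor: int = 8
) -> np.ndarray:
    """Normalized [0, 1] Gaussian random field, synthesized coarse."""
    from scipy.ndimage import zoom

    h, w = shape
    hs, ws = max(4, h // factor), max(4, w // factor)
    low = gaussian_filter(
        rng.standard_normal((hs, ws)), sigma=min(hs, ws) * rel_sigma, mode="nearest"
    )
    field = zoom(low, (h / hs, w / ws), order=3, mode="nearest")[:h, :w]
    if field.shape != (h, w):  # zoom can undershoot by a pixel
        out = np.empty((h, w))
        out[: field.shape[0], : field.shape[1]] = field
        out[field.shape[0] :, :] = out[field.shape[0] - 1 : field.shape[0], :]
        out[:, field.shape[1] :] = out[:, field.shape[1] - 1 : field.shape[1]]
        field = out
    return (field - field.min()) / max(np.ptp(field), 1e-12)


def _ellipse_polygon(
    center: np.ndarray, radii: np.ndarray, angle: float, n_vertices: int = 24
) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    dy = radii[0] * np.sin(t)
    dx = radii[1] * np.cos(t)
    c, s = np.cos(angle), np.sin(angle)
    rows = center[0] + c * dy - s * dx
    cols = center[1] + s * dy + c * dx
    return np.column_stack([rows, cols])


def _hex_sites(radius: float, spacing: float) -> np.ndarray:
    """Triangular-lattice offsets filling a disk of the given radius,
    ordered by distance from the disk center."""
    sites = []
    dy = spacing * np.sqrt(3) / 2.0
    n_rows = int(radius / dy) + 1
    for i in range(-n_rows, n_rows + 1):
        y = i * dy
        x_shift = (i % 2) * spacing / 2.0
        n_cols = int(radius / spacing) + 1
        for j in range(-n_cols, n_cols + 1):
            x = j * spacing + x_shift
            if y * y + x * x <= radius * radius:
                sites.append((y, x))
    sites = np.array(sites) if sites else np.empty((0, 2))
    order = np.argsort((sites**2).sum(axis=1))
    return sites[order]


def generate_phantom(
    canvas_size: tuple[int, int] = (1536, 1536),
    n_clusters: int = 4,
    cells_per_cluster: int = 12,
    n_singles: int = 10,
    pixel_size: float = 0.5,
    marker_strengths: dict[str, tuple[float, float]] | None = None,
    section_offsets: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    *,
    n_scatter_fields: int = 0,
    cells_per_field: int = 24,
    field_radius: float = 105.0,
    field_cell_gap: float = 10.0,
    cell_radius: tuple[float, float] = (9.0, 12.0),
    single_radius: tuple[float, float] = (13.0, 17.0),
    cluster_radius: float = 70.0,
    min_cell_separation: float = 4.0,
    cluster_style: str = "confluent",
    n_exclusions: int = 2,
    max_offset: int = 50,
) -> SlidePhantom:
    """Generate a seeded slide phantom with full ground truth.

    Exactly ``n_clusters * cells_per_cluster + n_singles +
    n_scatter_fields * cells_per_field`` trophoblast cells are placed.
    Clustered cells sit on a jittered triangular lattice inside disks of
    ``cluster_radius`` whose interior is fibrinoid (stroma-free), the way
    interstitial extravillous trophoblast clusters are embedded in the
    decidua; single cells (larger, giant-cell-like) lie in the stroma.
    Scatter fields model areas of moderate trophoblast invasion: disks of
    ``field_radius`` inside the stroma holding ``cells_per_field``
    non-touching cells at a looser lattice spacing (gap
    ``field_cell_gap``), which is what populates the low-density band with
    patches of substantial trophoblast fraction.  In the default
    ``"confluent"`` cluster style the space between clustered cells is
    filled with CK7-positive cytoplasm; the ``"discrete"`` style leaves
    the cells as separate disks, giving phantoms whose cells never touch
    so that connected-component counting has an exact truth.  An
    impossible packing request raises :class:`PackingError` rather than
    silently truncating.

    ``section_offsets`` default to (0, 0) for CK7 and seeded draws within
    ``±max_offset`` px for the other markers.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible phantoms")
    if cluster_style not in ("confluent", "discrete"):
        raise ValueError(f"unknown cluster_style {cluster_style!r}")
    h, w = canvas_size
    rng = np.random.default_rng([int(seed), 0x5119])
    r_lo, r_hi = cell_radius
    s_lo, s_hi = single_radius
    if r_lo <= 0 or r_hi < r_lo or s_lo <= 0 or s_hi < s_lo:
        raise ValueError("cell radii must satisfy 0 < min <= max")

    # coarse feasibility check before attempting placement
    demand = (
        n_clusters * np.pi * (cluster_radius + r_hi) ** 2
        + n_singles * np.pi * (2 * s_hi) ** 2
        + n_scatter_fields * np.pi * (field_radius + r_hi) ** 2
    )
    if demand > 0.5 * h * w:
        raise PackingError(
            f"{n_clusters} clusters (radius {cluster_radius}) + {n_singles} singles "
            f"do not fit a {h}x{w} canvas without mandatory overlap"
        )

    spacing = 2 * r_hi + min_cell_separation
    sites = _hex_sites(cluster_radius - r_hi, spacing)
    if cells_per_cluster > sites.shape[0]:
        raise PackingError(
            f"{cells_per_cluster} cells of radius <= {r_hi} with separation "
            f"{min_cell_separation} cannot pack into a cluster of radius {cluster_radius}"
        )

    margin = cluster_radius + r_hi + 2
    centers = _place_points(
        rng,
        n_clusters,
        np.array([margin, margin]),
        np.array([h - margin, w - margin]),
        min_dist=2 * cluster_radius + 4 * r_hi,
    )

    jitter = max(0.0, min_cell_separation / 2.0 - 1.0)
    cells = []
    clusters = []
    for k, center in enumerate(centers, start=1):
        clusters.append((center[0], center[1], cluster_radius))
        for site in sites[:cells_per_cluster]:
            p = center + site + rng.uniform(-jitter, jitter, size=2)
            cells.append((p[0], p[1], rng.uniform(r_lo, r_hi), k))

    # scattered low-density fields of non-touching cells inside the stroma
    field_sites = _hex_sites(field_radius - r_hi, 2 * r_hi + field_cell_gap)
    if n_scatter_fields and cells_per_field > field_sites.shape[0]:
        raise PackingError(
            f"{cells_per_field} cells cannot pack into a scatter field of "
            f"radius {field_radius} at gap {field_cell_gap}"
        )
    field_margin = field_radius + r_hi + 2
    field_centers = _place_points(
        rng,
        n_scatter_fields,
        np.array([field_margin, field_margin]),
        np.array([h - field_margin, w - field_margin]),
        min_dist=2 * field_radius,
        anchors=[
            (np.asarray(c), cluster_radius + field_radius + 4 * r_hi) for c in centers
        ],
    )
    field_jitter = max(0.0, field_cell_gap / 2.0 - 1.0)
    for center in field_centers:
        for site in field_sites[:cells_per_field]:
            p = center + site + rng.uniform(-field_jitter, field_jitter, size=2)
            cells.append((p[0], p[1], rng.uniform(r_lo, r_hi), SINGLE_CELL_ID))

    single_margin = s_hi + 2
    singles = _place_points(
        rng,
        n_singles,
        np.array([single_margin, single_margin]),
        np.array([h - single_margin, w - single_margin]),
        min_dist=2 * s_hi + min_cell_separation,
        anchors=[(np.asarray(c), cluster_radius + 2 * s_hi) for c in centers]
        + [(np.asarray(c), field_radius + 2 * s_hi) for c in field_centers],
    )
    for p in singles:
        cells.append((p[0], p[1], rng.uniform(s_lo, s_hi), SINGLE_CELL_ID))

    cell_arr = (
        np.array(cells, dtype=float) if cells else np.empty((0, 4), dtype=float)
    )
    cluster_arr = (
        np.array(clusters, dtype=float) if clusters else np.empty((0, 3), dtype=float)
    )

    # smooth stromal blob covering most of the canvas, with mild density
    # texture; cluster interiors are fibrinoid, hence stroma-free.  The
    # fields are synthesized at 1/8 resolution and upsampled — they only
    # need to be smooth at the ~100 px scale.
    base = _smooth_noise(rng, (h, w), rel_sigma=1 / 6.0)
    blob = binary_fill_holes(base > np.quantile(base, 0.25))
    texture = _smooth_noise(rng, (h, w), rel_sigma=1 / 14.0)
    stroma = np.where(blob, 0.7 + 0.3 * texture, 0.0)
    if cluster_arr.shape[0]:
        yy, xx = np.mgrid[0:h, 0:w]
        for cy, cx, cr in cluster_arr:
            stroma[(yy - cy) ** 2 + (xx - cx) ** 2 <= cr**2] = 0.0

    exclusions: list[tuple[str, np.ndarray]] = []
    labels = ["vessel", "gland", "muscle", "villous"]
    for i in range(n_exclusions):
        center = rng.uniform([0.15 * h, 0.15 * w], [0.85 * h, 0.85 * w])
        radii = rng.uniform(0.03, 0.06, size=2) * min(h, w)
        poly = _ellipse_polygon(center, radii, rng.uniform(0, np.pi))
        exclusions.append((labels[i % len(labels)], poly))
    covered = exclusion_raster((h, w), exclusions).mean()
    if covered > 0.30:
        raise PackingError(f"exclusion regions cover {covered:.0%} of the canvas")

    strengths = dict(_DEFAULT_MARKER_STRENGTHS if marker_strengths is None else marker_strengths)
    for m, (ts, ms) in strengths.items():
        if not (0.0 <= ts <= 1.0 and 0.0 <= ms <= 1.0):
            raise ValueError(f"marker_strengths[{m!r}] must lie in [0, 1]")

    if section_offsets is None:
        section_offsets = {}
        for m in strengths:
            if m == "CK7":
                section_offsets[m] = (0, 0)
            else:
                dy, dx = rng.integers(-max_offset * 3 // 5, max_offset * 3 // 5 + 1, size=2)
                section_offsets[m] = (int(dy), int(dx))
    for m, (dy, dx) in section_offsets.items():
        if abs(dy) > max_offset or abs(dx) > max_offset:
            raise ValueError(
                f"section offset {dy, dx} for {m!r} exceeds ±{max_offset} px"
            )

    return SlidePhantom(
        canvas_size=(h, w),
        pixel_size=float(pixel_size),
        trophoblast_cells=cell_arr,
        stroma_field=stroma,
        exclusion_regions=exclusions,
        marker_strengths=strengths,
        section_offsets={m: tuple(v) for m, v in section_offsets.items()},
        seed=int(seed),
        clusters=cluster_arr,
        cluster_style=cluster_style,
    )


def rasterize_cells(phantom: SlidePhantom, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Binary raster of all trophoblast disks (pixel inside iff its center
    lies within the disk radius)."""
    h, w = shape if shape is not None else phantom.canvas_size
    mask = np.zeros((h, w), dtype=bool)
    for cy, cx, r, _ in phantom.trophoblast_cells:
        y0, y1 = max(0, int(np.floor(cy - r)) - 1), min(h, int(np.ceil(cy + r)) + 2)
        x0, x1 = max(0, int(np.floor(cx - r)) - 1), min(w, int(np.ceil(cx + r)) + 2)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def exclusion_raster(
    shape: tuple[int, int], regions: list[tuple[str, np.ndarray]]
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for _, poly in regions:
        mask |= polygon2mask(shape, poly)
    return mask


def _shift_with_fill(arr: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """Integer translation with constant fill (content moves by (+dy, +dx))."""
    out = np.full_like(arr, fill)
    h, w = arr.shape[:2]
    ys0, ys1 = max(0, dy), min(h, h + dy)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    if ys0 >= ys1 or xs0 >= xs1:
        return out
    out[ys0:ys1, xs0:xs1] = arr[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def stain_maps(phantom: SlidePhantom, marker: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (hematoxylin OD, DAB OD) maps for one section, in the
    block's reference frame (before the section offset is applied)."""
    if marker not in phantom.marker_strengths:
        raise KeyError(f"marker {marker!r} not in phantom.marker_strengths")
    troph_s, maternal_s = phantom.marker_strengths[marker]
    cells = rasterize_cells(phantom)
    carpet = phantom.carpet_raster() & ~cells
    stroma = phantom.stroma_field
    excl = exclusion_raster(phantom.canvas_size, phantom.exclusion_regions)

    dab = np.where(cells, troph_s, maternal_s * stroma)
    dab = np.where(carpet, _CARPET_DAB * troph_s, dab)
    hema = np.where(cells, _HEMA_CELL, _HEMA_STROMA * (stroma > 0))
    hema = np.where(carpet, _HEMA_CARPET, hema)
    # excluded structures (vessels/glands) render as dense counterstained
    # tissue with nonspecific DAB — visually distinct, spatially annotated
    struct = excl & ~cells & ~carpet
    dab = np.where(struct, 0.5 * maternal_s, dab)
    hema = np.where(struct, 0.7, hema)
    return hema.astype(float), dab.astype(float)


def render_canvas(
    phantom: SlidePhantom,
    marker: str,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one full section canvas to uint8 RGB (no tiling, no vignette).

    Lambert-Beer: RGB = 255 · 10^−(c_H·v_H + c_DAB·v_DAB [+ ε]) with ε
    additive Gaussian noise of SD ``noise_sd`` in absorbance space, clipped
    to valid 8-bit range.  The section's rigid offset is applied here.
    """
    hema, dab = stain_maps(phantom, marker)
    dy, dx = phantom.section_offsets.get(marker, (0, 0))
    if (dy, dx) != (0, 0):
        hema = _shift_with_fill(hema, dy, dx)
        dab = _shift_with_fill(dab, dy, dx)

    stain_vecs = rgb_from_hdx.astype(np.float32)
    od_rgb = (
        hema.astype(np.float32)[..., None] * stain_vecs[0]
        + dab.astype(np.float32)[..., None] * stain_vecs[1]
    )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng([phantom.seed, _marker_tag(marker), 0x401])
        od_rgb += noise_sd * rng.standard_normal(od_rgb.shape, dtype=np.float32)
        np.maximum(od_rgb, 0.0, out=od_rgb)
    rgb = np.float32(255.0) * np.power(np.float32(10.0), -od_rgb)
    np.rint(rgb, out=rgb)
    return np.clip(rgb, 0, 255).astype(np.uint8)


def _marker_tag(marker: str) -> int:
    return int.from_bytes(marker.encode()[:4].ljust(4, b"\0"), "little") % (2**31)


def _vignette_field(
    shape: tuple[int, int], strength: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth radial-quadratic multiplicative shading with gain 1 at a
    randomly jittered optical center and minimum gain 1 − strength."""
    h, w = shape
    cy = rng.uniform(0.4, 0.6) * h
    cx = rng.uniform(0.4, 0.6) * w
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - cy) / h) ** 2 + ((xx - cx) / w) ** 2
    r2 = r2 / r2.max()
    return 1.0 - strength * r2


def tiling_layout(
    canvas_size: tuple[int, int], tile_shape: tuple[int, int], overlap: int
) -> tuple[int, int]:
    """Number of (rows, cols) of tiles needed to cover the canvas."""
    h, w = canvas_size
    th, tw = tile_shape
    if overlap < 0 or overlap >= min(th, tw):
        raise ValueError("overlap must satisfy 0 <= overlap < min(tile_shape)")
    rows = max(1, int(np.ceil((h - overlap) / (th - overlap))))
    cols = max(1, int(np.ceil((w - overlap) / (tw - overlap))))
    return rows, cols


def render_section(
    phantom: SlidePhantom,
    marker: str,
    vignette_strength: float = 0.0,
    noise_sd: float = 0.0,
    tile_shape: tuple[int, int] = (1536, 2048),
    overlap: int = 0,
) -> TileSet:
    """Render one marker section as a bright-field tile grid.

    The canvas is rendered with the marker's rigid offset, padded with white
    background to an exact tile grid, cut into ``tile_shape`` tiles with the
    requested overlap, and each tile is multiplied by the section's smooth
    shading field of amplitude ``vignette_strength`` (one optical field per
    section — vignetting originates in the scanner optics, so it is common
    to all tiles of a scan and independent of tile content).
    """
    if marker not in phantom.marker_strengths:
        raise KeyError(f"marker {marker!r} not in phantom.marker_strengths")
    if not (0.0 <= vignette_strength < 1.0):
        raise ValueError("vignette_strength must lie in [0, 1)")
    rng = np.random.default_rng([phantom.seed, _marker_tag(marker), 0x7711])
    canvas = render_canvas(phantom, marker, noise_sd=noise_sd, rng=rng)
    rows, cols = tiling_layout(phantom.canvas_size, tile_shape, overlap)
    th, tw = tile_shape
    full_h = rows * (th - overlap) + overlap
    full_w = cols * (tw - overlap) + overlap
    padded = np.full((full_h, full_w, 3), 255, dtype=np.uint8)
    padded[: canvas.shape[0], : canvas.shape[1]] = canvas

    gain = _vignette_field(tile_shape, vignette_strength, rng) if vignette_strength > 0 else None
    tiles = []
    for r in range(rows):
        for c in range(cols):
            y0 = r * (th - overlap)
            x0 = c * (tw - overlap)
            tile = padded[y0 : y0 + th, x0 : x0 + tw].astype(float)
            if gain is not None:
                tile = tile * gain[..., None]
            tiles.append(np.clip(np.rint(tile), 0, 255).astype(np.uint8))
    return TileSet(
        tiles=tiles,
        grid_layout=(rows, cols),
        overlap=overlap,
        pixel_size=phantom.pixel_size,
        marker=marker,
    )


def phantom_patch_truth(phantom: SlidePhantom, patch_size: int = 50):
    """Ground-truth patch table for the phantom's reference (CK7) frame.

    Per patch: true trophoblast pixel fraction over the patch area
    (``fraction``), the fraction over true tissue pixels matching the
    pipeline's denominator (``fraction_of_tissue``), the density-band class
    derived from the tissue fraction (0 → maternal, (0, 0.5] → low,
    (0.5, 1] → high), and whether the patch intersects an exclusion region.
    Partial edge patches are generated and flagged via ``area_px``.
    """
    import pandas as pd

    h, w = phantom.canvas_size
    cells = phantom.trophoblast_raster()
    tissue = phantom.tissue_truth()
    excl = exclusion_raster((h, w), phantom.exclusion_regions)

    rows = int(np.ceil(h / patch_size))
    cols = int(np.ceil(w / patch_size))
    records = []
    for r in range(rows):
        y0, y1 = r * patch_size, min((r + 1) * patch_size, h)
        for c in range(cols):
            x0, x1 = c * patch_size, min((c + 1) * patch_size, w)
            area = (y1 - y0) * (x1 - x0)
            n_cell = int(cells[y0:y1, x0:x1].sum())
            n_tissue = int(tissue[y0:y1, x0:x1].sum())
            frac_tissue = n_cell / n_tissue if n_tissue else 0.0
            records.append(
                {
                    "row": r,
                    "col": c,
                    "area_px": area,
                    "fraction": n_cell / area,
                    "fraction_of_tissue": frac_tissue,
                    "band": band_from_fraction(frac_tissue),
                    "excluded": bool(excl[y0:y1, x0:x1].any()),
                }
            )
    return pd.DataFrame.from_records(records)


def true_band_gray_means(
    phantom: SlidePhantom, marker: str, patch_size: int = 50
) -> dict[str, float]:
    """Ground-truth density-band gray means of one marker section.

    Computed from the phantom's ideal (noise-free, offset-free) stain
    model: per true patch, the mean Rec. 601 gray over true tissue pixels;
    per band, the mean of its patch means.  This is the reference the
    pipeline's measured band means are judged against.
    """
    hema, dab = stain_maps(phantom, marker)
    od_rgb = hema[..., None] * rgb_from_hdx[0] + dab[..., None] * rgb_from_hdx[1]
    rgb = 255.0 * np.power(10.0, -od_rgb)
    gray = rgb @ np.array([0.299, 0.587, 0.114])
    tissue = phantom.tissue_truth()

    h, w = phantom.canvas_size
    ys = np.arange(0, h, patch_size)
    xs = np.arange(0, w, patch_size)
    gsum = np.add.reduceat(np.add.reduceat(gray * tissue, ys, axis=0), xs, axis=1)
    npix = np.add.reduceat(
        np.add.reduceat(tissue.astype(np.int64), ys, axis=0), xs, axis=1
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        patch_means = np.where(npix > 0, gsum / np.maximum(npix, 1), np.nan)

    truth = phantom_patch_truth(phantom, patch_size)
    means = patch_means[truth["row"].to_numpy(), truth["col"].to_numpy()]
    out: dict[str, float] = {}
    for band in ("maternal", "low", "high"):
        sel = (truth["band"] == band).to_numpy() & np.isfinite(means)
        out[band] = float(np.mean(means[sel])) if sel.any() else float("nan")
    return out


def band_from_fraction(fraction: float) -> str:
    """Trophoblast density band: 0% → maternal, >0–50% → low, >50% → high.

    A fraction of exactly 0.5 is "low" (the high band is strictly >50%).
    """
    if fraction < 0 or fraction > 1:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction == 0:
        return "maternal"
    if fraction <= 0.5:
        return "low"
    return "high"
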