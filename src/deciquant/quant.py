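"""CK7-guided patch quantification of NRF2/KEAP1 staining intensity.

The core of the pipeline.  The CK7-stained reference section identifies
fetal extravillous trophoblasts by their DAB (brown) signal.  The scan is
tessellated into fixed-size patches (default 50 × 50 px) and each patch is
classified by its trophoblast area fraction into one of three density
bands: maternal tissue (0 % trophoblasts), low density (>0–50 %), and high
density (>50 %).  The serially sectioned NRF2 and KEAP1 scans are rigidly
aligned to the CK7 frame and their mean gray-level intensity (0 = black,
255 = white, Rec. 601 luma) is summarized per density band.  Staining
intensity is inversely proportional to protein expression; the gray scale
is reported as-is and never inverted internally.

Stain separation inverts the two-stain Lambert-Beer model with the fixed
H-DAB reference absorbance vectors (color deconvolution), yielding
non-negative per-pixel hematoxylin and DAB optical densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_opening, label as cc_label
from scipy.signal import fftconvolve
from skimage.color import hdx_from_rgb
from skimage.morphology import disk, remove_small_objects

from deciquant.phantom import band_from_fraction
from deciquant.stitching import SlideScan

__all__ = [
    "PatchGrid",
    "BandIntensitySummary",
    "RigidTransform",
    "BANDS",
    "separate_hdab",
    "ck7_positive_mask",
    "build_patch_grid",
    "count_trophoblasts",
    "register_sections",
    "quantify_intensity",
]

BANDS = ("maternal", "low", "high")

#: optical-density ceiling for saturated (near-black) pixels
OD_CEILING = 3.0


@dataclass
class RigidTransform:
    """Pure translation mapping a moving scan onto the reference frame.

    Applying ``(dy, dx)`` to the moving scan (content shifted down/right by
    positive values) superimposes it on the reference.  ``score`` is the
    normalized mask correlation at the optimum, in [0, 1].
    """

    dy: float
    dx: float
    score: float


@dataclass
class PatchGrid:
    """Tessellation of a scan into fixed-size patches.

    ``patches`` has one row per patch: grid indices, half-open pixel bounds,
    patch area, included-tissue and CK7-positive pixel counts, the
    trophoblast area fraction (over included tissue pixels), the density
    band, and an ``included`` flag (False when the patch holds no included
    tissue).  The band is a pure function of the fraction:
    0 → maternal, (0, 0.5] → low, (0.5, 1] → high.
    """

    patch_size: int
    shape: tuple[int, int]
    patches: pd.DataFrame
    included_mask: np.ndarray = field(repr=False)

    def band_counts(self) -> dict[str, int]:
        inc = self.patches[self.patches["included"]]
        return {b: int((inc["band"] == b).sum()) for b in BANDS}


@dataclass
class BandIntensitySummary:
    """Per-subject, per-marker density-banded intensity summary.

    Gray means are on the 0–255 scale (lower gray ⇒ stronger staining ⇒
    higher protein expression).  A band with no patches has mean NaN, never
    0.  ``overall_mean_gray`` averages the patch means of all included
    patches.
    """

    subject_id: str
    marker: str
    mean_gray: dict[str, float]
    n_patches: dict[str, int]
    overall_mean_gray: float
    trophoblast_count: int | None = None
    tissue_area_mm2: float | None = None
    trophoblast_density: float | None = None

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "marker": self.marker}
        for b in BANDS:
            row[f"mean_gray_{b}"] = self.mean_gray.get(b, float("nan"))
            row[f"n_patches_{b}"] = self.n_patches.get(b, 0)
        row["overall_mean_gray"] = self.overall_mean_gray
        row["trophoblast_count"] = self.trophoblast_count
        row["tissue_area_mm2"] = self.tissue_area_mm2
        row["trophoblast_density"] = self.trophoblast_density
        return row


def separate_hdab(scan: SlideScan) -> tuple[np.ndarray, np.ndarray]:
    """Color deconvolution of an H-DAB scan into stain optical densities.

    Per-channel OD is ``−log10(I/255)`` (pure white ⇒ OD exactly 0); the
    two-stain model is inverted with the standard H-DAB reference vectors.
    Negative stain estimates are clipped to 0 and saturated pixels to
    ``OD_CEILING``.  Returns (hematoxylin OD, DAB OD) rasters.
    """
    rgb = scan.image.astype(np.float32)
    transmittance = np.maximum(rgb, 1.0) / np.float32(255.0)
    od_rgb = -np.log10(transmittance)
    stains = od_rgb @ hdx_from_rgb.astype(np.float32)  # hematoxylin, DAB, residual
    hema = np.clip(stains[..., 0], 0.0, OD_CEILING)
    dab = np.clip(stains[..., 1], 0.0, OD_CEILING)
    return hema, dab


def ck7_positive_mask(
    dab_od: np.ndarray, od_threshold: float = 0.15, min_object_px: int = 20
) -> np.ndarray:
    """Threshold the DAB optical density and drop sub-cellular specks."""
    if od_threshold <= 0:
        raise ValueError("od_threshold must be positive")
    mask = dab_od >= od_threshold
    if min_object_px > 1 and mask.any():
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return mask


def build_patch_grid(
    scan_shape: tuple[int, int],
    patch_size: int,
    ck7_mask: np.ndarray,
    included_mask: np.ndarray,
) -> PatchGrid:
    """Tessellate the scan and classify each patch by trophoblast fraction.

    The fraction is CK7-positive pixels over included tissue pixels within
    the patch (not over total patch pixels), so partial edge patches and
    patches bordering background are not diluted.  Patches with no included
    tissue are flagged not-included and carry fraction 0.
    """
    h, w = scan_shape
    if ck7_mask.shape != (h, w) or included_mask.shape != (h, w):
        raise ValueError("masks must match the scan shape")
    ck7_inc = (ck7_mask & included_mask).astype(np.int64)
    inc = included_mask.astype(np.int64)

    ys = np.arange(0, h, patch_size)
    xs = np.arange(0, w, patch_size)
    # two-stage reduceat gives per-patch sums without a Python pixel loop
    tissue_px = np.add.reduceat(np.add.reduceat(inc, ys, axis=0), xs, axis=1)
    ck7_px = np.add.reduceat(np.add.reduceat(ck7_inc, ys, axis=0), xs, axis=1)

    rows, cols = np.meshgrid(np.arange(len(ys)), np.arange(len(xs)), indexing="ij")
    y0 = ys[rows]
    x0 = xs[cols]
    y1 = np.minimum(y0 + patch_size, h)
    x1 = np.minimum(x0 + patch_size, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tissue_px > 0, ck7_px / np.maximum(tissue_px, 1), 0.0)

    table = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "y0": y0.ravel(),
            "y1": y1.ravel(),
            "x0": x0.ravel(),
            "x1": x1.ravel(),
            "area_px": ((y1 - y0) * (x1 - x0)).ravel(),
            "tissue_px": tissue_px.ravel(),
            "ck7_px": ck7_px.ravel(),
            "trophoblast_fraction": frac.ravel(),
        }
    )
    table["band"] = [band_from_fraction(f) for f in table["trophoblast_fraction"]]
    table["included"] = table["tissue_px"] > 0
    return PatchGrid(
        patch_size=patch_size,
        shape=(h, w),
        patches=table,
        included_mask=included_mask.astype(bool),
    )


def count_trophoblasts(
    ck7_mask: np.ndarray,
    min_cell_px: int = 100,
    max_cell_px: int = 1200,
    area_mm2: float | None = None,
    opening_radius: int = 1,
) -> tuple[int, float | None]:
    """Count trophoblasts from the CK7 mask and derive the density.

    Connected components after a light morphological opening are counted;
    components below ``min_cell_px`` are debris and dropped, components
    above ``max_cell_px`` are touching-cell clusters and contribute
    ``round(area / median single-cell area)`` cells, where the typical
    single-cell area is the median of the single-sized components (the
    first mode of the component-area distribution).  Density is
    count / ``area_mm2`` (cells per mm² of included tissue).
    """
    if not (0 < min_cell_px < max_cell_px):
        raise ValueError("need 0 < min_cell_px < max_cell_px")
    mask = ck7_mask.astype(bool)
    if opening_radius > 0 and mask.any():
        mask = binary_opening(mask, structure=disk(opening_radius))
    labeled, n_comp = cc_label(mask)
    if n_comp == 0:
        count = 0
    else:
        areas = np.bincount(labeled.ravel())[1:]
        areas = areas[areas >= min_cell_px]
        singles = areas[areas <= max_cell_px]
        median_single = float(np.median(singles)) if singles.size else float("nan")
        count = int(singles.size)
        for a in areas[areas > max_cell_px]:
            if np.isfinite(median_single) and median_single > 0:
                count += max(1, int(round(a / median_single)))
            else:
                count += 1
    if area_mm2 is None:
        return count, None
    if area_mm2 <= 0:
        if count > 0:
            raise ValueError("nonzero trophoblast count with zero tissue area")
        return count, 0.0
    return count, count / area_mm2


def _lag_correlation(ref0: np.ndarray, mov0: np.ndarray, dy: int, dx: int) -> float:
    """Zero-mean correlation of two rasters at one integer lag of mov."""
    h, w = ref0.shape
    ys0, ys1 = max(0, dy), min(h, h + dy)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    if ys0 >= ys1 or xs0 >= xs1:
        return -np.inf
    a = ref0[ys0:ys1, xs0:xs1]
    b = mov0[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return float(np.dot(a.ravel(), b.ravel()))


def _best_lag(
    ref0: np.ndarray, mov0: np.ndarray, center: tuple[int, int], radius: int, limit: int
) -> tuple[int, int, float]:
    best = (-np.inf, 0, 0)
    for dy in range(center[0] - radius, center[0] + radius + 1):
        if abs(dy) > limit:
            continue
        for dx in range(center[1] - radius, center[1] + radius + 1):
            if abs(dx) > limit:
                continue
            c = _lag_correlation(ref0, mov0, dy, dx)
            if c > best[0]:
                best = (c, dy, dx)
    return best[1], best[2], best[0]


def register_sections(
    reference: SlideScan,
    moving: SlideScan,
    search_radius: int = 100,
    white_threshold: float = 230.0,
    score_floor: float = 0.2,
    reference_mask: np.ndarray | None = None,
    moving_mask: np.ndarray | None = None,
) -> RigidTransform:
    """Rigid (translation-only) alignment of a serial section to the
    reference, by maximizing the cross-correlation of the tissue masks.

    Serial 3 µm sections scanned on the same stage differ by a small shift
    only, so the search is restricted to ``±search_radius`` px.  The
    optimum is found coarse-to-fine: an FFT cross-correlation on 4×
    decimated masks proposes the lag, which is refined by direct search at
    2× and full resolution.  Returns the translation to apply to ``moving``
    and a normalized correlation score in [0, 1]; if the best score falls
    below ``score_floor`` the identity transform is returned with a
    warning.  Disjoint tissue (either mask empty) raises an error.
    Precomputed tissue masks can be supplied to avoid re-detection.
    """
    from deciquant.roi import tissue_mask

    if reference.pixel_size != moving.pixel_size:
        raise ValueError("scans must share pixel size")
    ref = (
        tissue_mask(reference, white_threshold=white_threshold)
        if reference_mask is None
        else reference_mask
    )
    mov = (
        tissue_mask(moving, white_threshold=white_threshold)
        if moving_mask is None
        else moving_mask
    )
    if ref.sum() == 0 or mov.sum() == 0:
        raise ValueError("cannot register scans with no detected tissue")
    ref0 = ref.astype(np.float32)
    mov0 = mov.astype(np.float32)
    ref0 -= ref0.mean()
    mov0 -= mov0.mean()

    # coarse FFT pass at 4x decimation
    ds = 4
    rs, ms = ref0[::ds, ::ds], mov0[::ds, ::ds]
    corr = fftconvolve(rs - rs.mean(), (ms - ms.mean())[::-1, ::-1], mode="full")
    cy, cx = ms.shape[0] - 1, ms.shape[1] - 1
    r_ds = max(1, search_radius // ds)
    y0, y1 = max(0, cy - r_ds), min(corr.shape[0], cy + r_ds + 1)
    x0, x1 = max(0, cx - r_ds), min(corr.shape[1], cx + r_ds + 1)
    window = corr[y0:y1, x0:x1]
    idx = np.unravel_index(np.argmax(window), window.shape)
    dy, dx = ds * (idx[0] + y0 - cy), ds * (idx[1] + x0 - cx)

    # refine: 2x grid around the coarse peak, then full resolution
    dy, dx, _ = _best_lag(
        ref0[::2, ::2], mov0[::2, ::2], (dy // 2, dx // 2), radius=3, limit=search_radius // 2
    )
    dy, dx = dy * 2, dx * 2
    dy, dx, corr_peak = _best_lag(ref0, mov0, (dy, dx), radius=2, limit=search_radius)

    denom = np.sqrt(float((ref0**2).sum()) * float((mov0**2).sum()))
    score = float(np.clip(corr_peak / max(denom, 1e-12), 0.0, 1.0))
    if score < score_floor:
        warnings.warn(
            f"registration score {score:.3f} below floor {score_floor}; "
            "returning identity transform",
            stacklevel=2,
        )
        return RigidTransform(0.0, 0.0, score)
    return RigidTransform(float(dy), float(dx), score)


def _apply_transform(image: np.ndarray, dy: int, dx: int, fill: int = 255) -> np.ndarray:
    out = np.full_like(image, fill)
    h, w = image.shape[:2]
    ys0, ys1 = max(0, dy), min(h, h + dy)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    if ys0 < ys1 and xs0 < xs1:
        out[ys0:ys1, xs0:xs1] = image[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def quantify_intensity(
    marker_scan: SlideScan,
    transform: RigidTransform,
    grid: PatchGrid,
    subject_id: str = "",
    trophoblast_count: int | None = None,
    tissue_area_mm2: float | None = None,
) -> BandIntensitySummary:
    """Density-banded gray-level intensity of a marker scan.

    The marker scan is moved into the CK7 grid frame by ``transform``
    (rounded to integer pixels), converted to Rec. 601 gray, and the mean
    gray of the included tissue pixels of every included patch is taken.
    Band means are patch-count-weighted averages of the patch means (each
    patch weighs 1); the overall mean averages all included patches.  Bands
    without patches are reported as NaN, not 0.
    """
    if marker_scan.shape != grid.shape:
        raise ValueError("marker scan shape does not match the patch grid")
    aligned = _apply_transform(
        marker_scan.image, int(round(transform.dy)), int(round(transform.dx))
    )
    gray = aligned.astype(float) @ np.array([0.299, 0.587, 0.114])

    inc = grid.included_mask
    h, w = grid.shape
    ys = np.arange(0, h, grid.patch_size)
    xs = np.arange(0, w, grid.patch_size)
    gsum = np.add.reduceat(np.add.reduceat(gray * inc, ys, axis=0), xs, axis=1)
    npix = np.add.reduceat(
        np.add.reduceat(inc.astype(np.int64), ys, axis=0), xs, axis=1
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        patch_means = np.where(npix > 0, gsum / np.maximum(npix, 1), np.nan)

    table = grid.patches
    means = patch_means[table["row"].to_numpy(), table["col"].to_numpy()]
    included = table["included"].to_numpy()

    mean_gray: dict[str, float] = {}
    n_patches: dict[str, int] = {}
    for band in BANDS:
        sel = included & (table["band"].to_numpy() == band)
        n_patches[band] = int(sel.sum())
        mean_gray[band] = float(np.mean(means[sel])) if sel.any() else float("nan")
    overall = float(np.mean(means[included])) if included.any() else float("nan")

    density = None
    if trophoblast_count is not None and tissue_area_mm2 is not None:
        if tissue_area_mm2 <= 0:
            if trophoblast_count > 0:
                raise ValueError("nonzero trophoblast count with zero tissue area")
            density = 0.0
        else:
            density = trophoblast_count / tissue_area_mm2
    return BandIntensitySummary(
        subject_id=subject_id,
        marker=marker_scan.marker,
        mean_gray=mean_gray,
        n_patches=n_patches,
        overall_mean_gray=overall,
        trophoblast_count=trophoblast_count,
        tissue_area_mm2=tissue_area_mm2,
        trophoblast_density=density,
    )
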