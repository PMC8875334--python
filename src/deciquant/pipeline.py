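"""End-to-end subject pipeline: tiles → scans → patch grid → band summaries.

Ties the stages together in the order used for every subject: flat-field
correction and stitching of each section's tiles, tissue detection and ROI
exclusion on the CK7 reference, stain separation and CK7 thresholding,
patch-grid construction, trophoblast counting, serial-section registration
of each marker scan, and density-banded intensity quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from deciquant.phantom import TileSet
from deciquant.quant import (
    BandIntensitySummary,
    PatchGrid,
    RigidTransform,
    build_patch_grid,
    ck7_positive_mask,
    count_trophoblasts,
    quantify_intensity,
    register_sections,
    separate_hdab,
)
from deciquant.roi import ROIMask, apply_roi, tissue_mask
from deciquant.stitching import SlideScan, correct_tiles, estimate_flatfield, stitch

__all__ = ["SubjectQuantification", "quantify_subject", "prepare_scan"]


@dataclass
class SubjectQuantification:
    """Everything the pipeline derives for one subject."""

    subject_id: str
    grid: PatchGrid
    summaries: dict[str, BandIntensitySummary]
    transforms: dict[str, RigidTransform]
    trophoblast_count: int
    tissue_area_mm2: float
    ck7_scan: SlideScan = field(repr=False)


def prepare_scan(tiles: TileSet, flatfield: bool = True) -> SlideScan:
    """Flat-field-correct (optionally) and stitch one section's tiles."""
    if flatfield:
        tiles = correct_tiles(tiles, estimate_flatfield(tiles))
    return stitch(tiles)


def quantify_subject(
    ck7_tiles: TileSet,
    marker_tiles: dict[str, TileSet],
    roi: ROIMask | None = None,
    subject_id: str = "",
    *,
    patch_size: int = 50,
    white_threshold: float = 230.0,
    od_threshold: float = 0.15,
    min_object_px: int = 20,
    min_cell_px: int = 100,
    max_cell_px: int = 1200,
    search_radius: int = 100,
    flatfield: bool = True,
) -> SubjectQuantification:
    """Run the full quantification for one subject.

    ``marker_tiles`` maps marker labels (e.g. NRF2, KEAP1) to their tile
    sets; each marker scan is registered to the CK7 reference before its
    intensity is summarized on the CK7-derived patch grid.
    """
    ck7_scan = prepare_scan(ck7_tiles, flatfield=flatfield)
    tissue = tissue_mask(ck7_scan, white_threshold=white_threshold)
    included, area_mm2 = apply_roi(tissue, roi or ROIMask([]), ck7_scan.pixel_size)

    _, dab = separate_hdab(ck7_scan)
    ck7_mask = ck7_positive_mask(dab, od_threshold=od_threshold, min_object_px=min_object_px)
    ck7_mask &= included

    grid = build_patch_grid(ck7_scan.shape, patch_size, ck7_mask, included)
    count, density = count_trophoblasts(
        ck7_mask, min_cell_px=min_cell_px, max_cell_px=max_cell_px, area_mm2=area_mm2
    )

    summaries: dict[str, BandIntensitySummary] = {}
    transforms: dict[str, RigidTransform] = {}
    for marker, tiles in marker_tiles.items():
        scan = prepare_scan(tiles, flatfield=flatfield)
        transform = register_sections(
            ck7_scan,
            scan,
            search_radius=search_radius,
            white_threshold=white_threshold,
            reference_mask=tissue,
        )
        transforms[marker] = transform
        summaries[marker] = quantify_intensity(
            scan,
            transform,
            grid,
            subject_id=subject_id,
            trophoblast_count=count,
            tissue_area_mm2=area_mm2,
        )
    return SubjectQuantification(
        subject_id=subject_id,
        grid=grid,
        summaries=summaries,
        transforms=transforms,
        trophoblast_count=count,
        tissue_area_mm2=area_mm2,
        ck7_scan=ck7_scan,
    )
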