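"""Reading and writing the pipeline's file formats.

Tile sets are numbered 8-bit RGB TIFFs with a plain-text YAML sidecar
(grid layout, overlap, pixel size, marker); stitched scans are single TIFFs
with a matching sidecar; patch tables and band summaries are CSV with a
``#``-prefixed provenance header; gene sets use the GMT tab format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from deciquant.phantom import TileSet
from deciquant.quant import BandIntensitySummary, PatchGrid
from deciquant.stitching import SlideScan

__all__ = [
    "write_tileset",
    "read_tileset",
    "write_scan",
    "read_scan",
    "write_patch_table",
    "write_band_summaries",
    "read_band_summaries",
    "read_gmt",
    "write_gmt",
]

_SIDECAR = "layout.yaml"


def write_tileset(tiles: TileSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows, cols = tiles.grid_layout
    for r in range(rows):
        for c in range(cols):
            tifffile.imwrite(directory / f"tile_r{r:02d}_c{c:02d}.tif", tiles.tile_at(r, c))
    sidecar = {
        "rows": rows,
        "cols": cols,
        "overlap": tiles.overlap,
        "pixel_size_um": float(tiles.pixel_size),
        "marker": tiles.marker,
    }
    (directory / _SIDECAR).write_text(yaml.safe_dump(sidecar))


def read_tileset(directory) -> TileSet:
    directory = Path(directory)
    meta = yaml.safe_load((directory / _SIDECAR).read_text())
    tiles = []
    for r in range(meta["rows"]):
        for c in range(meta["cols"]):
            path = directory / f"tile_r{r:02d}_c{c:02d}.tif"
            tiles.append(tifffile.imread(path) if path.exists() else None)
    return TileSet(
        tiles=tiles,
        grid_layout=(meta["rows"], meta["cols"]),
        overlap=meta["overlap"],
        pixel_size=meta["pixel_size_um"],
        marker=meta["marker"],
    )


def write_scan(scan: SlideScan, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, scan.image)
    sidecar = {
        "pixel_size_um": float(scan.pixel_size),
        "marker": scan.marker,
        "provenance": {k: _plain(v) for k, v in scan.provenance.items()},
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_scan(path) -> SlideScan:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return SlideScan(
        image=tifffile.imread(path),
        pixel_size=meta["pixel_size_um"],
        marker=meta["marker"],
        provenance=meta.get("provenance", {}),
    )


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


def _write_with_header(df: pd.DataFrame, path, provenance: dict) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in provenance.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def write_patch_table(grid: PatchGrid, path) -> None:
    _write_with_header(
        grid.patches, path, {"patch_size_px": grid.patch_size, "scan_shape": list(grid.shape)}
    )


def write_band_summaries(
    summaries: list[BandIntensitySummary], path, provenance: dict | None = None
) -> None:
    df = pd.DataFrame([s.to_row() for s in summaries])
    _write_with_header(df, path, provenance or {})


def read_band_summaries(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
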