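"""Georeferenced height rasters and 1-ha landscape aggregation.

A :class:`HeightRaster` is a single-band, axis-aligned grid of canopy heights
or terrain elevations in metres, with an affine transform and a nodata
sentinel.  GeoTIFF round-tripping is implemented directly on top of
:mod:`tifffile` using the standard geo tags (ModelPixelScale, ModelTiepoint,
GDAL_NODATA), which keeps values, transform and nodata mask bit-exact.

The :class:`HectareGrid` tiles a raster extent into 100 m x 100 m cells and
drives all landscape-scale summaries: canopy cover above a height threshold,
canopy volume (pixel height x pixel area, summed), and their per-decade
changes between two surveys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

DEFAULT_NODATA = -9999.0

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_METADATA = 42112
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """Axis-aligned affine transform: map coords of the grid's top-left corner
    plus positive pixel sizes.  y decreases with increasing row (north up)."""

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0", float(self.x0))
        object.__setattr__(self, "y0", float(self.y0))
        object.__setattr__(self, "dx", float(self.dx))
        object.__setattr__(self, "dy", float(self.dy))
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError(f"pixel size must be strictly positive, got {self.dx}x{self.dy}")

    def pixel_center(self, row, col):
        """Map coordinates of pixel centers (vectorised)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 - (np.asarray(row) + 0.5) * self.dy
        return x, y

    def world_to_pixel(self, x, y):
        """Fractional (row, col) of map coordinates."""
        col = (np.asarray(x) - self.x0) / self.dx
        row = (self.y0 - np.asarray(y)) / self.dy
        return row, col


@dataclass
class HeightRaster:
    """Single-band raster of heights (m) or elevations (m)."""

    values: np.ndarray
    transform: GridTransform
    crs: str = "local"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def shape(self):
        return self.values.shape

    @property
    def resolution(self):
        return (self.transform.dx, self.transform.dy)

    @property
    def pixel_area(self) -> float:
        return self.transform.dx * self.transform.dy

    def valid_mask(self) -> np.ndarray:
        v = self.values
        return np.isfinite(v) & (v != self.nodata)

    def masked(self) -> np.ndarray:
        """Values as float64 with nodata replaced by NaN."""
        out = self.values.astype(np.float64, copy=True)
        out[~self.valid_mask()] = np.nan
        return out

    def copy(self) -> "HeightRaster":
        return HeightRaster(self.values.copy(), self.transform, self.crs, self.nodata)

    def extent(self):
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        nrow, ncol = self.shape
        t = self.transform
        return (t.x0, t.y0 - nrow * t.dy, t.x0 + ncol * t.dx, t.y0)

    def sample(self, x, y):
        """Nearest-pixel values at map coordinates; raises if outside."""
        row, col = self.transform.world_to_pixel(x, y)
        r = np.floor(row).astype(int)
        c = np.floor(col).astype(int)
        nrow, ncol = self.shape
        if np.any((r < 0) | (r >= nrow) | (c < 0) | (c >= ncol)):
            raise ValueError("sample location outside raster extent")
        return self.values[r, c]


def write_raster(raster: HeightRaster, path) -> None:
    """Write a single-band GeoTIFF with pixel scale, tiepoint and nodata tags."""
    t = raster.transform
    meta_xml = f'<GDALMetadata>\n  <Item name="CRS">{raster.crs}</Item>\n</GDALMetadata>'
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.dx, t.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
        (_TAG_GDAL_METADATA, "s", None, meta_xml),
        (_TAG_GDAL_NODATA, "s", None, repr(float(raster.nodata))),
    ]
    tifffile.imwrite(path, raster.values, extratags=extratags, photometric="minisblack")


def read_raster(path) -> HeightRaster:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or any
    GeoTIFF carrying pixel-scale + tiepoint tags)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1 or len(tif.pages) > 1:
            raise ValueError(f"expected single-band raster: {path}")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"missing georeferencing tags in {path}")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tp = tags[_TAG_TIEPOINT].value
        # tiepoint maps raster (i, j) -> map (x, y); anchored at the corner here
        x0 = tp[3] - tp[0] * sx
        y0 = tp[4] + tp[1] * sy
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs = "local"
        if _TAG_GDAL_METADATA in tags:
            xml = tags[_TAG_GDAL_METADATA].value
            key = '<Item name="CRS">'
            if key in xml:
                crs = xml.split(key, 1)[1].split("</Item>", 1)[0]
        values = page.asarray()
    return HeightRaster(values, GridTransform(x0, y0, float(sx), float(sy)), crs, nodata)


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class AlignmentReport:
    compatible: bool
    reason: str
    row_offset: int = 0
    col_offset: int = 0
    overlap_shape: tuple = (0, 0)

    def __bool__(self) -> bool:
        return self.compatible


def check_alignment(a: HeightRaster, b: HeightRaster, tol: float = 1e-6) -> AlignmentReport:
    """Verify two rasters share a grid (same resolution, integer pixel offset)
    and report the overlap window.  Raises on incompatible resolution or
    empty overlap."""
    ta, tb = a.transform, b.transform
    if abs(ta.dx - tb.dx) > tol or abs(ta.dy - tb.dy) > tol:
        raise ValueError(
            f"incompatible resolutions: {ta.dx}x{ta.dy} vs {tb.dx}x{tb.dy}"
        )
    coff = (tb.x0 - ta.x0) / ta.dx
    roff = (ta.y0 - tb.y0) / ta.dy
    if abs(coff - round(coff)) > 1e-4 or abs(roff - round(roff)) > 1e-4:
        return AlignmentReport(False, "sub-pixel misalignment", 0, 0, (0, 0))
    roff, coff = int(round(roff)), int(round(coff))
    # overlap in a's pixel indices
    r0 = max(0, roff)
    c0 = max(0, coff)
    r1 = min(a.shape[0], roff + b.shape[0])
    c1 = min(a.shape[1], coff + b.shape[1])
    if r1 <= r0 or c1 <= c0:
        raise ValueError("rasters do not overlap")
    return AlignmentReport(True, "grids compatible", roff, coff, (r1 - r0, c1 - c0))


def clip_to_common(a: HeightRaster, b: HeightRaster):
    """Clip both rasters to their common extent (used to trim the later survey
    to the earlier one's footprint)."""
    rep = check_alignment(a, b)
    if not rep:
        raise ValueError(rep.reason)
    r0a, c0a = max(0, rep.row_offset), max(0, rep.col_offset)
    nr, nc = rep.overlap_shape
    r0b, c0b = r0a - rep.row_offset, c0a - rep.col_offset
    ta = a.transform
    new_t = GridTransform(ta.x0 + c0a * ta.dx, ta.y0 - r0a * ta.dy, ta.dx, ta.dy)
    ca = HeightRaster(a.values[r0a : r0a + nr, c0a : c0a + nc].copy(), new_t, a.crs, a.nodata)
    cb = HeightRaster(b.values[r0b : r0b + nr, c0b : c0b + nc].copy(), new_t, b.crs, b.nodata)
    return ca, cb


# ---------------------------------------------------------------------------
# hectare grid


@dataclass
class HectareGrid:
    """Tiling of a raster extent into square cells (1 ha by default),
    anchored at the raster origin.  Partial edge cells are kept but flagged."""

    transform: GridTransform
    raster_shape: tuple
    cell_size_m: float = 100.0
    mask: np.ndarray | None = None  # per-cell True = excluded habitat

    def __post_init__(self) -> None:
        nrow, ncol = self.raster_shape
        self.px_per_cell_x = self.cell_size_m / self.transform.dx
        self.px_per_cell_y = self.cell_size_m / self.transform.dy
        if abs(self.px_per_cell_x - round(self.px_per_cell_x)) > 1e-9 or abs(
            self.px_per_cell_y - round(self.px_per_cell_y)
        ) > 1e-9:
            raise ValueError("cell size must be an integer number of pixels")
        self.px_per_cell_x = int(round(self.px_per_cell_x))
        self.px_per_cell_y = int(round(self.px_per_cell_y))
        self.n_cell_rows = math.ceil(nrow / self.px_per_cell_y)
        self.n_cell_cols = math.ceil(ncol / self.px_per_cell_x)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_cell_rows, self.n_cell_cols):
                raise ValueError("mask shape must match the cell grid")

    @property
    def n_cells(self) -> int:
        return self.n_cell_rows * self.n_cell_cols

    def cell_slices(self, cr: int, cc: int):
        r0 = cr * self.px_per_cell_y
        c0 = cc * self.px_per_cell_x
        r1 = min(r0 + self.px_per_cell_y, self.raster_shape[0])
        c1 = min(c0 + self.px_per_cell_x, self.raster_shape[1])
        return slice(r0, r1), slice(c0, c1)

    def is_partial(self, cr: int, cc: int) -> bool:
        rs, cs = self.cell_slices(cr, cc)
        return (rs.stop - rs.start) * (cs.stop - cs.start) != self.px_per_cell_x * self.px_per_cell_y

    def is_masked(self, cr: int, cc: int) -> bool:
        return bool(self.mask[cr, cc]) if self.mask is not None else False

    def cell_of_point(self, x, y):
        """Cell (row, col) containing map coordinates (vectorised)."""
        row, col = self.transform.world_to_pixel(x, y)
        cr = np.floor(np.asarray(row) / self.px_per_cell_y).astype(int)
        cc = np.floor(np.asarray(col) / self.px_per_cell_x).astype(int)
        return cr, cc

    @classmethod
    def for_raster(cls, raster: HeightRaster, cell_size_m: float = 100.0,
                   mask_raster: HeightRaster | None = None) -> "HectareGrid":
        mask = None
        if mask_raster is not None:
            grid = cls(raster.transform, raster.shape, cell_size_m)
            mask = np.zeros((grid.n_cell_rows, grid.n_cell_cols), dtype=bool)
            for cr in range(grid.n_cell_rows):
                for cc in range(grid.n_cell_cols):
                    rs, cs = grid.cell_slices(cr, cc)
                    mask[cr, cc] = np.nanmean(mask_raster.values[rs, cs]) > 0.5
        return cls(raster.transform, raster.shape, cell_size_m, mask)


def _check_grid_matches(chm: HeightRaster, cells: HectareGrid) -> None:
    if chm.shape != cells.raster_shape:
        raise ValueError("raster shape does not match the hectare grid")


def _cell_apply(chm: HeightRaster, cells: HectareGrid, fn) -> pd.DataFrame:
    _check_grid_matches(chm, cells)
    vals = chm.masked()
    rows = []
    for cr in range(cells.n_cell_rows):
        for cc in range(cells.n_cell_cols):
            rs, cs = cells.cell_slices(cr, cc)
            block = vals[rs, cs]
            valid = np.isfinite(block)
            n_valid = int(valid.sum())
            stat = fn(block[valid]) if n_valid else np.nan
            rows.append(
                dict(
                    cell_row=cr,
                    cell_col=cc,
                    n_pixels=block.size,
                    n_valid=n_valid,
                    partial=cells.is_partial(cr, cc),
                    masked=cells.is_masked(cr, cc),
                    all_nodata=n_valid == 0,
                    value=stat,
                )
            )
    return pd.DataFrame(rows)


def canopy_cover(chm: HeightRaster, cells: HectareGrid, threshold_m: float = 4.0) -> pd.DataFrame:
    """Per-cell % of valid pixels strictly exceeding ``threshold_m``.

    Nodata pixels are excluded from the denominator; a fully-nodata cell is
    flagged (``all_nodata``) rather than reported as 0%.
    """
    if threshold_m < 0:
        raise ValueError("threshold must be >= 0")
    df = _cell_apply(chm, cells, lambda v: 100.0 * np.mean(v > threshold_m))
    return df.rename(columns={"value": "cover_pct"})


def canopy_volume(chm: HeightRaster, cells: HectareGrid) -> pd.DataFrame:
    """Per-cell canopy volume (m^3): pixel height x pixel area, summed."""
    area = chm.pixel_area
    df = _cell_apply(chm, cells, lambda v: float(v.sum()) * area)
    return df.rename(columns={"value": "volume_m3"})


def delta_metrics(
    chm_t1: HeightRaster,
    chm_t2: HeightRaster,
    cells: HectareGrid,
    interval_years: float,
) -> pd.DataFrame:
    """Per-cell change in canopy cover (% per decade, >4 m) and canopy volume
    (m^3 per decade) between two aligned surveys.  Changes are t2 - t1 scaled
    linearly by 10 / interval_years."""
    rep = check_alignment(chm_t1, chm_t2)
    if not rep or rep.row_offset != 0 or rep.col_offset != 0 or chm_t1.shape != chm_t2.shape:
        raise ValueError("surveys must be on an identical grid")
    if interval_years <= 0:
        raise ValueError("interval must be positive")
    scale = 10.0 / interval_years
    c1 = canopy_cover(chm_t1, cells)
    c2 = canopy_cover(chm_t2, cells)
    v1 = canopy_volume(chm_t1, cells)
    v2 = canopy_volume(chm_t2, cells)
    out = c1[["cell_row", "cell_col", "n_pixels", "n_valid", "partial", "masked", "all_nodata"]].copy()
    out["cover_t1_pct"] = c1["cover_pct"]
    out["cover_t2_pct"] = c2["cover_pct"]
    out["volume_t1_m3"] = v1["volume_m3"]
    out["volume_t2_m3"] = v2["volume_m3"]
    out["d_cover_pct_decade"] = (c2["cover_pct"] - c1["cover_pct"]) * scale
    out["d_vol_m3_decade"] = (v2["volume_m3"] - v1["volume_m3"]) * scale
    return out


def cell_table_to_raster(
    table: pd.DataFrame,
    cells: HectareGrid,
    column: str,
    nodata: float = DEFAULT_NODATA,
) -> HeightRaster:
    """Turn a per-cell summary column into a coarse (cell-sized) raster,
    e.g. for writing 100-m GeoTIFF maps of hectare statistics."""
    vals = np.full((cells.n_cell_rows, cells.n_cell_cols), nodata, dtype=np.float32)
    for _, row in table.iterrows():
        r, c = int(row["cell_row"]), int(row["cell_col"])
        if 0 <= r < cells.n_cell_rows and 0 <= c < cells.n_cell_cols:
            v = row[column]
            if pd.notna(v) and not (("masked" in row) and row["masked"]):
                vals[r, c] = v
    t = cells.transform
    coarse = GridTransform(t.x0, t.y0, cells.cell_size_m, cells.cell_size_m)
    return HeightRaster(vals, coarse, "local", nodata)


def aggregate_tree_rates(
    trees: pd.DataFrame,
    cells: HectareGrid,
    interval_years: float,
) -> pd.DataFrame:
    """Aggregate per-tree demography to the hectare grid.

    ``trees`` needs columns x, y, status, dh_decade, da_decade, dagb_decade_kg
    (growth columns may be NaN for dead trees).  Returns one row per cell with
    mean growth of survivors, mortality (% per decade, linear scaling) and net
    biomass change (Mg per decade summed over the cell's trees).
    """
    cr, cc = cells.cell_of_point(trees["x"].to_numpy(), trees["y"].to_numpy())
    t = trees.copy()
    t["cell_row"], t["cell_col"] = cr, cc
    scale = 10.0 / interval_years
    rows = []
    for (r, c), g in t.groupby(["cell_row", "cell_col"]):
        surv = g[g["status"] == "survived"]
        dead = g[g["status"] == "dead_or_dieback"]
        n_fate = len(surv) + len(dead)
        rows.append(
            dict(
                cell_row=r,
                cell_col=c,
                n_trees=len(g),
                masked=cells.is_masked(r, c) if 0 <= r < cells.n_cell_rows and 0 <= c < cells.n_cell_cols else True,
                mean_dh_decade=surv["dh_decade"].mean() if len(surv) else np.nan,
                mean_da_decade=surv["da_decade"].mean() if len(surv) else np.nan,
                mortality_pct_decade=100.0 * len(dead) / n_fate * scale if n_fate else np.nan,
                net_dagb_mg_decade=g["dagb_decade_kg"].sum(min_count=1) / 1000.0,
            )
        )
    return pd.DataFrame(rows)
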