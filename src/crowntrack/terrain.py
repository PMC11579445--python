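"""Topographic and neighbourhood covariates for individual trees.

Topographic wetness index (TWI) is computed on the 5-m terrain model as
``ln(a / tan(beta))`` where ``a`` is the specific catchment area (upslope
contributing area per unit contour width, with contour width taken as the
cell size) and ``beta`` the local slope.  Flow is routed with a
multiple-flow-direction (MFD) scheme: each cell passes its accumulated area
to all lower 8-neighbours with weights proportional to the downslope
gradient.  A single-direction (D8) variant is provided and used as an
independent cross-check.  Terrain is sink-filled by priority flood before
routing, the standard prerequisite for wetness indices.

Neighbourhood competition is summarised as the mean canopy height within a
25-m buffer around each crown's perimeter (a size-symmetric proxy of local
stand basal area); the focal crown's own pixels are excluded by default.
"""

from __future__ import annotations

import heapq

import numpy as np
import shapely

from .raster import HeightRaster

# 8-neighbour offsets and their centre-to-centre distances (in cell units)
_OFFS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_DIST = np.array([np.hypot(dr, dc) for dr, dc in _OFFS])


def fill_sinks(dtm: HeightRaster, epsilon: float = 1e-6) -> HeightRaster:
    """Priority-flood depression filling with a tiny gradient ``epsilon`` so
    every interior cell drains to the boundary."""
    z = dtm.masked()
    if np.isnan(z).any():
        raise ValueError("DTM contains nodata holes; fill or clip before routing")
    nrow, ncol = z.shape
    filled = np.full_like(z, np.inf)
    visited = np.zeros(z.shape, dtype=bool)
    heap = []
    count = 0
    for r in range(nrow):
        for c in range(ncol):
            if r in (0, nrow - 1) or c in (0, ncol - 1):
                filled[r, c] = z[r, c]
                heapq.heappush(heap, (z[r, c], count, r, c))
                count += 1
                visited[r, c] = True
    while heap:
        zv, _, r, c = heapq.heappop(heap)
        for dr, dc in _OFFS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and not visited[rr, cc]:
                visited[rr, cc] = True
                filled[rr, cc] = max(z[rr, cc], filled[r, c] + epsilon)
                heapq.heappush(heap, (filled[rr, cc], count, rr, cc))
                count += 1
    return HeightRaster(filled, dtm.transform, dtm.crs, dtm.nodata)


def _downslope_weights(z: np.ndarray, r: int, c: int, cell: float):
    nrow, ncol = z.shape
    nbrs, grads = [], []
    for k, (dr, dc) in enumerate(_OFFS):
        rr, cc = r + dr, c + dc
        if 0 <= rr < nrow and 0 <= cc < ncol:
            g = (z[r, c] - z[rr, cc]) / (_DIST[k] * cell)
            if g > 0:
                nbrs.append((rr, cc))
                grads.append(g)
    return nbrs, np.asarray(grads)


def flow_accumulation(dtm: HeightRaster, routing: str = "mfd"):
    """Contributing area (m^2, including the cell itself) for every cell of a
    sink-filled DTM.

    Returns ``(accum, outflow)`` where ``outflow`` is the total area delivered
    to cells with no downslope neighbour (domain sinks/edges); conservation
    demands ``outflow == n_cells * cell_area``.
    """
    if routing not in ("mfd", "d8"):
        raise ValueError("routing must be 'mfd' or 'd8'")
    z = dtm.masked()
    if np.isnan(z).any():
        raise ValueError("DTM contains nodata holes; fill or clip before routing")
    cell = dtm.transform.dx
    cell_area = dtm.pixel_area
    nrow, ncol = z.shape
    accum = np.full(z.shape, float(cell_area))
    order = np.argsort(z, axis=None, kind="stable")[::-1]  # high to low
    outflow = 0.0
    for idx in order:
        r, c = divmod(int(idx), ncol)
        nbrs, grads = _downslope_weights(z, r, c, cell)
        if not nbrs:
            outflow += accum[r, c]
            continue
        if routing == "d8":
            k = int(np.argmax(grads))
            accum[nbrs[k]] += accum[r, c]
        else:
            w = grads / grads.sum()
            for (rr, cc), wi in zip(nbrs, w):
                accum[rr, cc] += wi * accum[r, c]
    return accum, outflow


def slope_tangent(dtm: HeightRaster, min_slope: float = 0.001) -> np.ndarray:
    """Slope tan(beta) by central differences, floored at ``min_slope``."""
    z = dtm.masked()
    gy, gx = np.gradient(z, dtm.transform.dy, dtm.transform.dx)
    return np.maximum(np.hypot(gx, gy), min_slope)


def compute_twi(
    dtm: HeightRaster,
    routing: str = "mfd",
    min_slope: float = 0.001,
    fill: bool = True,
) -> HeightRaster:
    """Topographic wetness index ln(a / tan beta) on the DTM grid.

    ``a`` is specific catchment area: flow accumulation (m^2, cell included)
    divided by the contour width (one cell size).
    """
    filled = fill_sinks(dtm) if fill else dtm
    accum, _ = flow_accumulation(filled, routing=routing)
    a = accum / filled.transform.dx
    tanb = slope_tangent(filled, min_slope=min_slope)
    twi = np.log(a / tanb)
    return HeightRaster(twi, dtm.transform, dtm.crs, dtm.nodata)


# ---------------------------------------------------------------------------
# per-tree covariates


def _pixels_in_geom(raster: HeightRaster, geom) -> np.ndarray:
    """Values of pixels whose centers fall inside ``geom`` (boundary exclusive)."""
    xmin, ymin, xmax, ymax = geom.bounds
    t = raster.transform
    c0 = max(0, int(np.floor((xmin - t.x0) / t.dx)))
    c1 = min(raster.shape[1], int(np.ceil((xmax - t.x0) / t.dx)) + 1)
    r0 = max(0, int(np.floor((t.y0 - ymax) / t.dy)))
    r1 = min(raster.shape[0], int(np.ceil((t.y0 - ymin) / t.dy)) + 1)
    if r1 <= r0 or c1 <= c0:
        return np.array([])
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    x, y = t.pixel_center(rows.ravel(), cols.ravel())
    inside = shapely.contains_xy(geom, x, y)
    vals = raster.values[rows.ravel()[inside], cols.ravel()[inside]].astype(float)
    return vals[np.isfinite(vals) & (vals != raster.nodata)]


def neighbourhood_height(
    crown_polygon,
    chm: HeightRaster,
    buffer_m: float = 25.0,
    exclude_focal: bool = True,
) -> float:
    """Mean CHM height (m) in a ``buffer_m`` annulus around a crown polygon.

    The annulus is the buffered polygon minus the focal crown (the inclusive
    variant keeps the focal pixels).  Crowns near the raster edge use the
    clipped buffer.  Raises on an empty annulus.
    """
    buffered = crown_polygon.buffer(buffer_m)
    region = buffered.difference(crown_polygon) if exclude_focal else buffered
    vals = _pixels_in_geom(chm, region)
    if vals.size == 0:
        raise ValueError("empty neighbourhood annulus (crown outside raster?)")
    return float(vals.mean())


def pulse_density_difference(
    pd_t2: HeightRaster,
    pd_t1: HeightRaster,
    x,
    y,
) -> np.ndarray:
    """Pulse-density difference (t2 - t1, pulses per m^2) sampled at tree
    locations.  Rasters must share a grid; locations must fall inside it."""
    if pd_t1.shape != pd_t2.shape or pd_t1.transform != pd_t2.transform:
        raise ValueError("pulse-density rasters must share a grid")
    return np.asarray(pd_t2.sample(x, y), dtype=float) - np.asarray(pd_t1.sample(x, y), dtype=float)
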