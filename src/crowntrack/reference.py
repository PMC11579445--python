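"""Slow, transparent reference implementations used for validation.

These deliberately avoid the data structures of the production code (no
heaps, no vectorised filters): seeds come from an explicit double loop over
pixels, region growth from a linear scan that repeatedly picks the highest
pending pixel, and D8 accumulation from an elevation-sorted pass.  They
exist so the fast implementations can be checked for exact agreement on
small grids.
"""

from __future__ import annotations

import numpy as np

from .raster import HeightRaster
from .segmentation import SegmentationParams, Seed


def brute_force_seeds(chm: HeightRaster, params: SegmentationParams, window_scale: float) -> list:
    """Window-maximum scan written as plain loops."""
    vals = chm.masked()
    nrow, ncol = vals.shape
    res = chm.transform.dx
    out = []
    for r in range(nrow):
        for c in range(ncol):
            h = vals[r, c]
            if not np.isfinite(h) or h < params.min_tree_height_m:
                continue
            radius = max(1, round(window_scale * (params.window_c * h**params.window_d + params.window_floor_m) / 2.0 / res))
            is_seed = True
            tied = False
            for rr in range(max(0, r - radius), min(nrow, r + radius + 1)):
                for cc in range(max(0, c - radius), min(ncol, c + radius + 1)):
                    if (rr, cc) == (r, c) or (rr - r) ** 2 + (cc - c) ** 2 > radius * radius:
                        continue
                    v = vals[rr, cc]
                    if not np.isfinite(v):
                        continue
                    if v > h or (v == h and (rr, cc) < (r, c)):
                        is_seed = False
                    elif v == h:
                        tied = True
            if is_seed:
                out.append(Seed(r, c, float(h), tied))
    return out


def flood_fill_regions(chm: HeightRaster, seeds: list, params: SegmentationParams) -> np.ndarray:
    """Region growth by linear scan: the pending pixel with the greatest
    height (earliest insertion on ties) is processed next, with the same
    join rules as the production grower."""
    vals = chm.masked()
    valid = np.isfinite(vals)
    nrow, ncol = vals.shape
    labels = np.full(vals.shape, -1, dtype=int)
    res = chm.transform.dx
    sums = [0.0] * len(seeds)
    counts = [0] * len(seeds)
    max_r2 = [(params.max_crown_diameter_m(s.height) / 2.0 / res) ** 2 for s in seeds]

    pending = []  # (height, insertion, r, c, region)
    counter = 0

    def push_neighbours(r, c, k):
        nonlocal counter
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and valid[rr, cc] and labels[rr, cc] == -1:
                pending.append((vals[rr, cc], counter, rr, cc, k))
                counter += 1

    for k, s in enumerate(seeds):
        if valid[s.row, s.col] and labels[s.row, s.col] == -1:
            labels[s.row, s.col] = k
            sums[k] += vals[s.row, s.col]
            counts[k] += 1
            push_neighbours(s.row, s.col, k)

    while pending:
        best = 0
        for i in range(1, len(pending)):
            h_i, n_i = pending[i][0], pending[i][1]
            h_b, n_b = pending[best][0], pending[best][1]
            if h_i > h_b or (h_i == h_b and n_i < n_b):
                best = i
        h, _, r, c, k = pending.pop(best)
        if labels[r, c] != -1:
            continue
        if h <= params.th_seed * seeds[k].height:
            continue
        if h <= params.th_cr * (sums[k] / counts[k]):
            continue
        if (r - seeds[k].row) ** 2 + (c - seeds[k].col) ** 2 > max_r2[k]:
            continue
        labels[r, c] = k
        sums[k] += h
        counts[k] += 1
        push_neighbours(r, c, k)
    return labels


def d8_accumulation_by_sorting(dtm: HeightRaster) -> np.ndarray:
    """Single-direction flow accumulation (m^2) by an explicit descending
    elevation sweep; each cell sends everything to its steepest lower
    8-neighbour."""
    z = dtm.masked()
    nrow, ncol = z.shape
    cell = dtm.transform.dx
    cell_area = dtm.pixel_area
    accum = np.full(z.shape, cell_area)
    cells = sorted(
        ((z[r, c], r, c) for r in range(nrow) for c in range(ncol)),
        key=lambda t: -t[0],
    )
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for zv, r, c in cells:
        best = None
        best_grad = 0.0
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol:
                grad = (zv - z[rr, cc]) / (np.hypot(dr, dc) * cell)
                if grad > best_grad:
                    best_grad = grad
                    best = (rr, cc)
        if best is not None:
            accum[best] += accum[r, c]
    return accum
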