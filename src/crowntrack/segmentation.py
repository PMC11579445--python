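"""Two-stage individual tree crown detection and delineation on a CHM.

Seeding and growth follow the classic local-maxima / region-growing scheme
for canopy height models: a pixel seeds a crown when it is the strict
maximum of a circular window whose diameter scales allometrically with the
pixel's height, and crowns are grown outwards from the seeds with
height-threshold rules.  The two-stage configuration runs a first pass with
a broad search window so large crowns are captured whole (avoiding
oversegmentation), masks the claimed pixels, and then runs a second pass
with a smaller window to pick up small trees missed in the first pass.

Pixel-processing order during growth is a single global height-descending
queue across all regions (ties broken by insertion order), so results are
deterministic and independently reproducible by a brute-force reference
implementation (see :mod:`crowntrack.reference`).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage

from .raster import HeightRaster


@dataclass
class SegmentationParams:
    """Tuning knobs for seeding and region growth.

    The seed-window function gives a window *diameter* in metres as a
    function of pixel height: ``w(h) = window_c * h**window_d + window_floor_m``.
    The two passes scale this by ``broad_window_scale`` and
    ``small_window_scale``.  ``max_crown_scale`` caps each crown's diameter at
    that multiple of its seed's allometric width.
    """

    min_tree_height_m: float = 4.0
    min_crown_area_m2: float = 9.0
    window_c: float = 1.45
    window_d: float = 0.90
    window_floor_m: float = 1.5
    broad_window_scale: float = 1.3
    small_window_scale: float = 0.6
    th_seed: float = 0.45
    th_cr: float = 0.55
    max_crown_scale: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.th_seed < 1 and 0 < self.th_cr < 1):
            raise ValueError("th_seed and th_cr must be in (0, 1)")
        if self.broad_window_scale <= self.small_window_scale:
            raise ValueError("broad window must exceed the small window")
        if self.window_c <= 0 or self.window_floor_m < 0 or self.max_crown_scale <= 0:
            raise ValueError("window parameters must be positive")

    def window_diameter_m(self, h) -> np.ndarray:
        return self.window_c * np.asarray(h, dtype=float) ** self.window_d + self.window_floor_m

    def max_crown_diameter_m(self, seed_height: float) -> float:
        return self.max_crown_scale * float(self.window_diameter_m(seed_height))


@dataclass
class Seed:
    row: int
    col: int
    height: float
    tied: bool = False


@dataclass
class CrownRecord:
    """One delineated crown: exact pixel-boundary polygon plus summary
    dimensions (H = max CHM in crown, CD from area assuming a circle)."""

    crown_id: int
    survey: str
    polygon: shapely.Polygon
    apex_xy: tuple
    height_m: float
    area_m2: float
    rows: np.ndarray = field(repr=False, default=None)
    cols: np.ndarray = field(repr=False, default=None)

    @property
    def crown_diameter_m(self) -> float:
        return 2.0 * math.sqrt(self.area_m2 / math.pi)


def _disc_offsets(radius_px: int):
    """Window offsets (excluding the centre) within a Euclidean radius."""
    r = int(radius_px)
    offs = []
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if (dr or dc) and dr * dr + dc * dc <= r * r:
                offs.append((dr, dc))
    return offs


def _disc_footprint(radius_px: int) -> np.ndarray:
    r = int(radius_px)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr * dr + dc * dc) <= r * r


def detect_seeds(chm: HeightRaster, params: SegmentationParams, window_scale: float) -> list:
    """Local-maxima seeds with a height-dependent circular window.

    A pixel of height h is a seed when it is >= min_tree_height and the
    strict maximum of the circular window of diameter
    ``window_scale * w(h)`` centred on it; among tied maxima the first pixel
    in scan order wins (``Seed.tied`` records the tie).
    """
    vals = chm.masked()
    valid = np.isfinite(vals)
    z = np.where(valid, vals, -np.inf)
    res = chm.transform.dx
    cand_mask = z >= params.min_tree_height_m
    if not cand_mask.any():
        return []
    # cheap prefilter: every seed must at least dominate its 4-neighbourhood
    local4 = ndimage.maximum_filter(z, footprint=_disc_footprint(1), mode="constant", cval=-np.inf)
    rows, cols = np.nonzero(cand_mask & (z >= local4))

    nrow, ncol = z.shape
    seeds: list[Seed] = []
    for r, c in zip(rows, cols):
        v = z[r, c]
        radius = max(1, round(window_scale * float(params.window_diameter_m(v)) / 2.0 / res))
        r0, r1 = max(0, r - radius), min(nrow, r + radius + 1)
        c0, c1 = max(0, c - radius), min(ncol, c + radius + 1)
        block = z[r0:r1, c0:c1]
        dr, dc = np.mgrid[r0 - r : r1 - r, c0 - c : c1 - c]
        in_disc = (dr * dr + dc * dc <= radius * radius) & ((dr != 0) | (dc != 0))
        wvals = block[in_disc]
        if wvals.size and wvals.max() > v:
            continue
        tied = bool(wvals.size and (wvals == v).any())
        if tied:
            # first pixel in scan order among tied maxima wins
            tr, tc = dr[in_disc & (block == v)], dc[in_disc & (block == v)]
            if np.any((tr < 0) | ((tr == 0) & (tc < 0))):
                continue
        seeds.append(Seed(int(r), int(c), float(v), tied))
    seeds.sort(key=lambda s: (s.row, s.col))
    return seeds


def grow_regions(chm: HeightRaster, seeds: list, params: SegmentationParams) -> np.ndarray:
    """Grow crowns from seeds; returns an int label grid (-1 = unclaimed).

    A pixel joins region k iff (all at the moment it is popped from the
    queue): it is unclaimed, its height exceeds ``th_seed`` x seed height and
    ``th_cr`` x the region's current mean height, and its centre lies within
    ``max_crown_diameter/2`` of the seed.  The queue is global and
    height-descending (4-neighbour growth); ties resolve by insertion order.
    """
    vals = chm.masked()
    valid = np.isfinite(vals)
    nrow, ncol = vals.shape
    labels = np.full(vals.shape, -1, dtype=np.int32)
    res = chm.transform.dx

    seed_h = [s.height for s in seeds]
    seed_rc = [(s.row, s.col) for s in seeds]
    max_r2_px = [
        (params.max_crown_diameter_m(h) / 2.0 / res) ** 2 for h in seed_h
    ]
    sums = [0.0] * len(seeds)
    counts = [0] * len(seeds)

    heap: list = []
    counter = 0
    for k, s in enumerate(seeds):
        if labels[s.row, s.col] != -1 or not valid[s.row, s.col]:
            continue
        labels[s.row, s.col] = k
        sums[k] += vals[s.row, s.col]
        counts[k] += 1
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = s.row + dr, s.col + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and valid[rr, cc] and labels[rr, cc] == -1:
                heapq.heappush(heap, (-vals[rr, cc], counter, rr, cc, k))
                counter += 1

    while heap:
        negh, _, r, c, k = heapq.heappop(heap)
        if labels[r, c] != -1:
            continue
        h = -negh
        if h <= params.th_seed * seed_h[k]:
            continue
        if h <= params.th_cr * (sums[k] / counts[k]):
            continue
        sr, sc = seed_rc[k]
        if (r - sr) ** 2 + (c - sc) ** 2 > max_r2_px[k]:
            continue
        labels[r, c] = k
        sums[k] += h
        counts[k] += 1
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and valid[rr, cc] and labels[rr, cc] == -1:
                heapq.heappush(heap, (-vals[rr, cc], counter, rr, cc, k))
                counter += 1
    return labels


def label_polygon(labels: np.ndarray, label: int, transform) -> shapely.Polygon:
    """Exact pixel-boundary polygon (union of pixel squares) of one region."""
    rows, cols = np.nonzero(labels == label)
    return pixels_polygon(rows, cols, transform)


def pixels_polygon(rows, cols, transform) -> shapely.Polygon:
    t = transform
    xmin = t.x0 + cols * t.dx
    xmax = xmin + t.dx
    ymax = t.y0 - rows * t.dy
    ymin = ymax - t.dy
    boxes = shapely.box(xmin, ymin, xmax, ymax)
    return shapely.coverage_union_all(boxes)


def two_stage_segment(chm: HeightRaster, params: SegmentationParams, survey: str = "") -> list:
    """Broad-window pass, mask claimed pixels, small-window second pass.

    Returns the union of both passes as :class:`CrownRecord` objects, keeping
    only crowns strictly taller than ``min_tree_height_m`` with a crown area
    strictly greater than ``min_crown_area_m2``.  Regions never overlap,
    within or across passes.
    """
    seeds1 = detect_seeds(chm, params, params.broad_window_scale)
    labels1 = grow_regions(chm, seeds1, params)

    masked_vals = chm.values.astype(np.float64, copy=True)
    masked_vals[labels1 >= 0] = chm.nodata
    masked = HeightRaster(masked_vals, chm.transform, chm.crs, chm.nodata)
    seeds2 = detect_seeds(masked, params, params.small_window_scale)
    labels2 = grow_regions(masked, seeds2, params)

    records: list[CrownRecord] = []
    pixel_area = chm.pixel_area
    vals = chm.masked()
    next_id = 0
    for labels, seeds in ((labels1, seeds1), (labels2, seeds2)):
        flat = labels.ravel()
        pos = np.argsort(flat, kind="stable")
        sorted_flat = flat[pos]
        ks = np.arange(len(seeds))
        starts = np.searchsorted(sorted_flat, ks, side="left")
        stops = np.searchsorted(sorted_flat, ks, side="right")
        for k, s in enumerate(seeds):
            idx = pos[starts[k] : stops[k]]
            if idx.size == 0:
                continue
            rows, cols = np.unravel_index(idx, labels.shape)
            area = idx.size * pixel_area
            height = float(np.nanmax(vals[rows, cols]))
            if not (height > params.min_tree_height_m and area > params.min_crown_area_m2):
                continue
            poly = pixels_polygon(rows, cols, chm.transform)
            ax, ay = chm.transform.pixel_center(s.row, s.col)
            records.append(
                CrownRecord(next_id, survey, poly, (float(ax), float(ay)), height, float(area), rows, cols)
            )
            next_id += 1
    return records


# ---------------------------------------------------------------------------
# benchmarking


@dataclass
class SegmentationBenchmark:
    n_reference: int
    n_detected: int
    pct_correct: float
    pct_oversegmented: float
    pct_omitted: float
    mean_iou_pct: float
    mean_matched_area_m2: float
    precision: float
    recall: float
    f1: float


def benchmark_segmentation(
    predicted: list,
    reference: list,
    iou_threshold: float = 0.5,
    minor_overlap: float = 0.1,
) -> SegmentationBenchmark:
    """Score a segmentation against reference crowns.

    Predicted and reference crowns are matched one-to-one greedily by
    decreasing IoU.  A reference crown is *correct* when its match exceeds
    the IoU cut-off (strict >), *oversegmented* when two or more predictions
    each cover more than ``minor_overlap`` of its area without a correct
    match, and *omitted* when nothing overlaps it.  Precision is
    correct / predicted, recall is correct / reference.
    """
    if not reference:
        raise ValueError("benchmark undefined for an empty reference set")
    ref_polys = [c.polygon for c in reference]
    pred_polys = [c.polygon for c in predicted]
    tree = shapely.STRtree(pred_polys) if pred_polys else None

    pairs = []  # (iou, ref_idx, pred_idx, overlap_frac_of_ref)
    overlaps_per_ref = [[] for _ in reference]
    for i, rp in enumerate(ref_polys):
        if tree is None:
            continue
        for j in tree.query(rp):
            inter = rp.intersection(pred_polys[j]).area
            if inter <= 0:
                continue
            union = rp.area + pred_polys[j].area - inter
            pairs.append((inter / union, i, int(j)))
            overlaps_per_ref[i].append(inter / rp.area)

    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    ref_match = {}
    pred_used = set()
    for iou, i, j in pairs:
        if i in ref_match or j in pred_used:
            continue
        ref_match[i] = (j, iou)
        pred_used.add(j)

    n_ref = len(reference)
    correct = [i for i, (_, iou) in ref_match.items() if iou > iou_threshold]
    overseg = [
        i
        for i in range(n_ref)
        if i not in correct and sum(1 for f in overlaps_per_ref[i] if f > minor_overlap) >= 2
    ]
    omitted = [i for i in range(n_ref) if not overlaps_per_ref[i]]

    ious = [iou for _, iou in ref_match.values()]
    matched_areas = [pred_polys[j].area for j, _ in ref_match.values()]
    n_pred = len(predicted)
    precision = len(correct) / n_pred if n_pred else 0.0
    recall = len(correct) / n_ref
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return SegmentationBenchmark(
        n_reference=n_ref,
        n_detected=n_pred,
        pct_correct=100.0 * len(correct) / n_ref,
        pct_oversegmented=100.0 * len(overseg) / n_ref,
        pct_omitted=100.0 * len(omitted) / n_ref,
        mean_iou_pct=100.0 * float(np.mean(ious)) if ious else 0.0,
        mean_matched_area_m2=float(np.mean(matched_areas)) if matched_areas else 0.0,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def crowns_to_geojson(crowns: list, path) -> None:
    """Write crowns as a GeoJSON FeatureCollection with id/survey/H/A/CD."""
    import json

    features = []
    for c in crowns:
        features.append(
            {
                "type": "Feature",
                "geometry": shapely.geometry.mapping(c.polygon),
                "properties": {
                    "id": c.crown_id,
                    "survey": c.survey,
                    "height_m": c.height_m,
                    "area_m2": c.area_m2,
                    "crown_diameter_m": c.crown_diameter_m,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
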