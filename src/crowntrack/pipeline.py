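"""End-to-end orchestration: CHM pair -> matched, covariate-laden tree table.

Thin glue over the stage modules so the analysis scripts, the tests and the
acceptance machinery all execute the identical sequence: two-stage
segmentation of both surveys, centroid matching with ambiguity filtering,
fate classification at the 30% decline rule, per-decade growth increments,
biomass change under the crown allometries, and per-tree covariates (TWI,
25-m neighbourhood height, pulse-density difference).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import allometry, matching, segmentation, terrain
from .raster import HeightRaster


def demography_table(
    chm_t1: HeightRaster,
    chm_t2: HeightRaster,
    params: segmentation.SegmentationParams,
    interval_years: float,
    dtm: HeightRaster | None = None,
    twi: HeightRaster | None = None,
    pulse_t1: HeightRaster | None = None,
    pulse_t2: HeightRaster | None = None,
    allom: allometry.AllometryParams | None = None,
    neighbourhood_buffer_m: float = 25.0,
) -> dict:
    """Run the full tree-tracking pipeline on a pair of aligned CHMs.

    Returns a dict with the crown lists, the matched-tree objects and a
    per-tree DataFrame carrying fates, growth rates, biomass changes and
    (when terrain/pulse rasters are given) the model covariates.
    """
    crowns_t1 = segmentation.two_stage_segment(chm_t1, params, "t1")
    crowns_t2 = segmentation.two_stage_segment(chm_t2, params, "t2")
    pairing = matching.match_crowns(crowns_t1, crowns_t2)
    matched = matching.classify_fate(pairing, crowns_t1, crowns_t2, chm_t1, chm_t2)
    matching.growth_increments(matched, interval_years)
    trees = matching.matched_to_dataframe(matched)
    if len(trees):
        trees = allometry.append_agb_columns(trees, interval_years, allom)

    if twi is None and dtm is not None:
        twi = terrain.compute_twi(dtm)
    if len(trees) and twi is not None:
        trees["twi"] = np.asarray(twi.sample(trees["x"].to_numpy(), trees["y"].to_numpy()), dtype=float)
    if len(trees) and pulse_t1 is not None and pulse_t2 is not None:
        trees["pulse_density_diff"] = terrain.pulse_density_difference(
            pulse_t2, pulse_t1, trees["x"].to_numpy(), trees["y"].to_numpy()
        )
    if len(trees):
        nh = np.full(len(trees), np.nan)
        for k, t in enumerate(matched):
            nh[k] = terrain.neighbourhood_height(t.crown_t1.polygon, chm_t1, neighbourhood_buffer_m)
        trees["neighbourhood_height"] = nh
        trees["size"] = trees["size_t1_m2"]
        trees["died"] = (trees["status"] == matching.STATUS_DEAD).astype(float)

    return {
        "crowns_t1": crowns_t1,
        "crowns_t2": crowns_t2,
        "pairing": pairing,
        "matched": matched,
        "trees": trees,
    }
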