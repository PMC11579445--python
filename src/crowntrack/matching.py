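"""Cross-survey crown matching, fate classification and growth increments.

A first-survey crown matches a second-survey crown when its polygon contains
the later crown's centroid (boundary points count as outside).  Any crown in
either survey that contains two or more centroids from the other survey
flags oversegmentation, and every tree involved is excluded as ambiguous
rather than risking extreme spurious growth values.  A matched tree that
lost >= 30% of its height and/or crown area is classed as dead or having
undergone severe dieback; an unmatched first-survey crown whose in-polygon
CHM maximum dropped by >= 30% likewise; an unmatched crown whose height is
essentially unchanged is presumed a segmentation omission and excluded
(unresolved).  Survivors get height and crown-area increments scaled
linearly to per-decade rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .raster import HeightRaster
from .segmentation import CrownRecord
from .terrain import _pixels_in_geom

STATUS_SURVIVED = "survived"
STATUS_DEAD = "dead_or_dieback"
STATUS_AMBIGUOUS = "ambiguous_excluded"
STATUS_UNRESOLVED = "unresolved"


@dataclass
class MatchedTree:
    """A first-survey crown and its fate."""

    crown_t1: CrownRecord
    crown_t2: CrownRecord | None
    status: str
    h_t1: float = np.nan
    h_t2: float = np.nan
    a_t1: float = np.nan
    a_t2: float = np.nan
    mean_h_t1: float = np.nan   # mean-CHM height variant, stored for comparison
    mean_h_t2: float = np.nan
    dh_decade: float = np.nan
    da_decade: float = np.nan
    dagb_decade_kg: float = np.nan


@dataclass
class Pairing:
    """Output of :func:`match_crowns`."""

    pairs: dict           # t1 crown_id -> t2 crown_id (one-to-one)
    ambiguous_t1: set     # t1 ids excluded by the multi-centroid rule
    unmatched_t1: list    # t1 ids with no centroid match
    recruitment_t2: list  # t2 ids unclaimed by any t1 crown (counted only)


def match_crowns(crowns_t1: list, crowns_t2: list) -> Pairing:
    """Pair crowns across surveys by polygon-contains-centroid.

    Containment is boundary-exclusive (a centroid on a shared boundary
    belongs to no crown), which with pixel-disjoint crowns makes each t2
    centroid claimable by at most one t1 crown.
    """
    id_t1 = [c.crown_id for c in crowns_t1]
    if not crowns_t1 or not crowns_t2:
        return Pairing({}, set(), list(id_t1), [c.crown_id for c in crowns_t2])

    polys_t1 = [c.polygon for c in crowns_t1]
    tree_t1 = shapely.STRtree(polys_t1)
    centroids_t2 = [c.polygon.centroid for c in crowns_t2]

    # forward: which t1 crown contains each t2 centroid ("within" is
    # boundary-exclusive, giving the documented tie rule for free)
    contains: dict[int, list[int]] = {}
    for j, pt in enumerate(centroids_t2):
        for i in tree_t1.query(pt, predicate="within"):
            contains.setdefault(int(i), []).append(j)
    # reverse: which t2 crown contains each t1 centroid (oversegmentation in t1)
    tree_t2 = shapely.STRtree([c.polygon for c in crowns_t2])
    rev_counts = np.zeros(len(crowns_t2), dtype=int)
    rev_members: dict[int, list[int]] = {}
    for i, c in enumerate(crowns_t1):
        pt = c.polygon.centroid
        for j in tree_t2.query(pt, predicate="within"):
            rev_counts[int(j)] += 1
            rev_members.setdefault(int(j), []).append(i)

    ambiguous_t1: set[int] = set()
    pairs: dict[int, int] = {}
    matched_t2: set[int] = set()
    for i, js in contains.items():
        if len(js) >= 2:  # t1 crown holds several t2 centroids
            ambiguous_t1.add(crowns_t1[i].crown_id)
            matched_t2.update(js)
            continue
        j = js[0]
        pairs[crowns_t1[i].crown_id] = crowns_t2[j].crown_id
        matched_t2.add(j)
    # t2 crowns containing >= 2 t1 centroids poison their pairs
    for j, members in rev_members.items():
        if rev_counts[j] >= 2:
            for i in members:
                tid = crowns_t1[i].crown_id
                ambiguous_t1.add(tid)
                pairs.pop(tid, None)

    unmatched = [c.crown_id for c in crowns_t1 if c.crown_id not in pairs and c.crown_id not in ambiguous_t1]
    recruitment = [crowns_t2[j].crown_id for j in range(len(crowns_t2)) if j not in matched_t2]
    return Pairing(pairs, ambiguous_t1, unmatched, recruitment)


def _crown_heights(crown: CrownRecord, chm: HeightRaster):
    """(max, mean) CHM height inside a crown's footprint."""
    if crown.rows is not None:
        nrow, ncol = chm.shape
        if crown.rows.max() >= nrow or crown.cols.max() >= ncol:
            raise ValueError("crown footprint outside the CHM")
        vals = chm.masked()[crown.rows, crown.cols]
        vals = vals[np.isfinite(vals)]
    else:
        vals = _pixels_in_geom(chm, crown.polygon)
    if vals.size == 0:
        raise ValueError("crown polygon fully outside the CHM")
    return float(vals.max()), float(vals.mean())


def classify_fate(
    pairing: Pairing,
    crowns_t1: list,
    crowns_t2: list,
    chm_t1: HeightRaster,
    chm_t2: HeightRaster,
    threshold: float = 0.30,
) -> list:
    """Assign every first-survey crown a fate.

    Matched pairs: relative decline ``(v1 - v2)/v1 >= threshold`` in height
    or crown area (either suffices, boundary inclusive) means dead/dieback,
    otherwise survived.  Unmatched t1 crowns are overlaid on both CHMs; a
    height decline >= threshold means dead/dieback, anything less is
    unresolved.  Ambiguous crowns pass through excluded.
    """
    by_id_t2 = {c.crown_id: c for c in crowns_t2}
    out: list[MatchedTree] = []
    for c1 in crowns_t1:
        if c1.crown_id in pairing.ambiguous_t1:
            out.append(MatchedTree(c1, None, STATUS_AMBIGUOUS))
            continue
        if c1.crown_id in pairing.pairs:
            c2 = by_id_t2[pairing.pairs[c1.crown_id]]
            decline_h = (c1.height_m - c2.height_m) / c1.height_m
            decline_a = (c1.area_m2 - c2.area_m2) / c1.area_m2
            status = STATUS_DEAD if (decline_h >= threshold or decline_a >= threshold) else STATUS_SURVIVED
            _, mh1 = _crown_heights(c1, chm_t1)
            _, mh2 = _crown_heights(c2, chm_t2)
            out.append(
                MatchedTree(
                    c1, c2, status,
                    h_t1=c1.height_m, h_t2=c2.height_m,
                    a_t1=c1.area_m2, a_t2=c2.area_m2,
                    mean_h_t1=mh1, mean_h_t2=mh2,
                )
            )
        else:
            h1, mh1 = _crown_heights(c1, chm_t1)
            h2, mh2 = _crown_heights(c1, chm_t2)
            decline = (h1 - h2) / h1
            status = STATUS_DEAD if decline >= threshold else STATUS_UNRESOLVED
            out.append(
                MatchedTree(
                    c1, None, status,
                    h_t1=h1, h_t2=h2, a_t1=c1.area_m2,
                    mean_h_t1=mh1, mean_h_t2=mh2,
                )
            )
    return out


def growth_increments(trees: list, interval_years: float) -> list:
    """Fill per-decade height and crown-area increments for survivors.

    Negative increments short of the mortality bar are legitimate shrinkage
    and are retained.  Raises if asked to compute a rate for a non-survivor.
    """
    scale = 10.0 / interval_years
    for t in trees:
        if t.status == STATUS_SURVIVED:
            _increment(t, scale)
    return trees


def _increment(tree: MatchedTree, scale: float) -> None:
    if tree.status != STATUS_SURVIVED:
        raise ValueError("growth increments are defined for survivors only")
    tree.dh_decade = (tree.h_t2 - tree.h_t1) * scale
    tree.da_decade = (tree.a_t2 - tree.a_t1) * scale


def matched_to_dataframe(trees: list) -> pd.DataFrame:
    """One row per first-survey crown."""
    rows = []
    for t in trees:
        cx, cy = t.crown_t1.polygon.centroid.x, t.crown_t1.polygon.centroid.y
        rows.append(
            dict(
                crown_id_t1=t.crown_t1.crown_id,
                crown_id_t2=t.crown_t2.crown_id if t.crown_t2 is not None else -1,
                x=cx,
                y=cy,
                status=t.status,
                h_t1=t.h_t1,
                h_t2=t.h_t2,
                a_t1=t.a_t1,
                a_t2=t.a_t2,
                cd_t1=t.crown_t1.crown_diameter_m,
                mean_h_t1=t.mean_h_t1,
                mean_h_t2=t.mean_h_t2,
                dh_decade=t.dh_decade,
                da_decade=t.da_decade,
                dagb_decade_kg=t.dagb_decade_kg,
            )
        )
    return pd.DataFrame(rows)


def fate_agreement(matched_trees: list, truth_trees: pd.DataFrame) -> dict:
    """Score fate classification against a synthetic scene's ground truth.

    Each first-survey crown is attributed to the truth tree whose stem falls
    inside its polygon (unique when crowns are disjoint and hard-core
    separated).  Agreement is the fraction of attributed, fate-classified
    crowns whose predicted class (survived vs dead/dieback) matches the
    truth ``died`` flag; ambiguous/unresolved crowns count as disagreements
    in ``agreement_all`` but are excluded from ``agreement_classified``.
    """
    stems = shapely.points(truth_trees["x"].to_numpy(), truth_trees["y"].to_numpy())
    tree = shapely.STRtree(stems)
    n_attr = n_agree = n_class = n_agree_class = 0
    for t in matched_trees:
        hits = tree.query(t.crown_t1.polygon, predicate="contains")
        if len(hits) != 1:
            continue
        truth_died = bool(truth_trees["died"].iloc[int(hits[0])])
        n_attr += 1
        if t.status in (STATUS_SURVIVED, STATUS_DEAD):
            n_class += 1
            ok = (t.status == STATUS_DEAD) == truth_died
            n_agree_class += ok
            n_agree += ok
    return {
        "n_attributed": n_attr,
        "n_classified": n_class,
        "agreement_all": n_agree / n_attr if n_attr else np.nan,
        "agreement_classified": n_agree_class / n_class if n_class else np.nan,
    }


def mortality_rate_variants(n_dead: int, n_total: int, interval_years: float) -> dict:
    """Raw interval fraction plus linear and compound per-decade scalings (%).

    The per-decade convention for a 9-yr census interval is not unique, so
    all three are reported side by side.
    """
    if n_total <= 0:
        raise ValueError("no fate-classified trees")
    raw = n_dead / n_total
    return {
        "raw_fraction_pct": 100.0 * raw,
        "linear_pct_per_decade": 100.0 * raw * 10.0 / interval_years,
        "compound_pct_per_decade": 100.0 * (1.0 - (1.0 - raw) ** (10.0 / interval_years)),
    }
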