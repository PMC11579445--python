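"""Crown-dimension allometry, biomass accounting and size-class summaries.

Stem diameter is predicted from height and crown diameter with the
Australasian woodland/savanna crown allometry
``DBH = 0.519 * (H * CD)^0.890 * CF_DBH`` (CF the Baskerville log-back-
transform correction), and aboveground biomass with the eucalypt model
``AGB = 0.133 * DBH^2.375 * CF_AGB``.  Dead or severely died-back trees are
assumed to lose all their biomass by the second survey.

Tree size throughout is the product H x CD (m^2) from the first survey;
trees are grouped either into 10 equal-width bins of log(H x CD) (the
right-skew-friendly choice for rate curves) or into 10 percentile bins of
equal count (for partitioning biomass stocks, gains and losses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .matching import STATUS_DEAD, STATUS_SURVIVED


@dataclass
class AllometryParams:
    dbh_coef: float = 0.519
    dbh_exp: float = 0.890
    cf_dbh: float = 1.002
    agb_coef: float = 0.133
    agb_exp: float = 2.375
    cf_agb: float = 1.067

    def __post_init__(self) -> None:
        if min(self.dbh_coef, self.dbh_exp, self.cf_dbh, self.agb_coef, self.agb_exp, self.cf_agb) <= 0:
            raise ValueError("allometry parameters must be positive")


def size_metric(h, cd):
    """Tree size H x CD (m^2), the crown-based biomass correlate."""
    return np.asarray(h, dtype=float) * np.asarray(cd, dtype=float)


def estimate_dbh(h, cd, params: AllometryParams | None = None):
    """Stem diameter (cm) from height (m) and crown diameter (m)."""
    params = params or AllometryParams()
    h = np.asarray(h, dtype=float)
    cd = np.asarray(cd, dtype=float)
    if np.any(h <= 0) or np.any(cd <= 0):
        raise ValueError("height and crown diameter must be positive")
    return params.dbh_coef * (h * cd) ** params.dbh_exp * params.cf_dbh


def estimate_agb(dbh_cm, params: AllometryParams | None = None):
    """Aboveground biomass (kg) from stem diameter (cm)."""
    params = params or AllometryParams()
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("DBH must be positive")
    return params.agb_coef * dbh**params.agb_exp * params.cf_agb


def tree_agb(h, cd, params: AllometryParams | None = None):
    return estimate_agb(estimate_dbh(h, cd, params), params)


def append_agb_columns(
    trees: pd.DataFrame,
    interval_years: float,
    params: AllometryParams | None = None,
) -> pd.DataFrame:
    """Add agb_t1_kg, agb_t2_kg and dagb_decade_kg to a matched-tree table.

    Survivors change by (AGB_t2 - AGB_t1) * 10/interval; dead trees lose all
    their first-survey biomass (AGB_t2 = 0).  Ambiguous and unresolved trees
    keep NaN (excluded, not zeroed).
    """
    params = params or AllometryParams()
    t = trees.copy()
    cd1 = 2.0 * np.sqrt(t["a_t1"] / np.pi)
    t["size_t1_m2"] = size_metric(t["h_t1"], cd1)
    t["agb_t1_kg"] = tree_agb(t["h_t1"], cd1, params)
    scale = 10.0 / interval_years
    agb2 = np.full(len(t), np.nan)
    surv = t["status"] == STATUS_SURVIVED
    dead = t["status"] == STATUS_DEAD
    cd2 = 2.0 * np.sqrt(t.loc[surv, "a_t2"] / np.pi)
    agb2[surv.to_numpy()] = tree_agb(t.loc[surv, "h_t2"], cd2, params)
    agb2[dead.to_numpy()] = 0.0
    t["agb_t2_kg"] = agb2
    t["dagb_decade_kg"] = (t["agb_t2_kg"] - t["agb_t1_kg"]) * scale
    return t


# ---------------------------------------------------------------------------
# size binning


def bin_trees(sizes, mode: str, n_bins: int = 10) -> np.ndarray:
    """Assign each size (H x CD, m^2) to a class; returns bin indices 0..n-1.

    ``log_equal_width``: equal-width bins of log(size) spanning [min, max],
    last bin right-inclusive.  ``percentile``: decile cut points with equal
    counts; a value tied with a cut point goes to the lower bin.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size < n_bins:
        raise ValueError(f"need at least {n_bins} trees to form {n_bins} bins")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    if mode == "log_equal_width":
        logs = np.log(sizes)
        lo, hi = logs.min(), logs.max()
        if hi - lo <= 0:
            raise ValueError("zero size range: log binning undefined")
        idx = np.floor((logs - lo) / (hi - lo) * n_bins).astype(int)
        return np.minimum(idx, n_bins - 1)
    if mode == "percentile":
        cuts = np.quantile(sizes, np.linspace(0, 1, n_bins + 1)[1:-1])
        if len(np.unique(cuts)) != len(cuts):
            raise ValueError("degenerate percentile cuts (too many ties)")
        return np.searchsorted(cuts, sizes, side="left")
    raise ValueError("mode must be 'log_equal_width' or 'percentile'")


def bin_edges(sizes, mode: str, n_bins: int = 10) -> np.ndarray:
    sizes = np.asarray(sizes, dtype=float)
    if mode == "log_equal_width":
        return np.exp(np.linspace(np.log(sizes.min()), np.log(sizes.max()), n_bins + 1))
    if mode == "percentile":
        return np.quantile(sizes, np.linspace(0, 1, n_bins + 1))
    raise ValueError("unknown mode")


def _mean_ci(x: np.ndarray):
    """Mean with normal-theory 95% CI."""
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan, np.nan, np.nan
    m = float(x.mean())
    if x.size < 2:
        return m, np.nan, np.nan
    half = stats.t.ppf(0.975, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
    return m, m - half, m + half


def _mortality_ci(n_dead: int, n: int):
    """Proportion with a logit-scale 95% CI; Jeffreys interval at 0 or 1
    deaths where the logit interval degenerates."""
    p = n_dead / n
    if 0 < n_dead < n:
        logit = np.log(p / (1 - p))
        se = np.sqrt(1.0 / (n * p * (1 - p)))
        lo = 1 / (1 + np.exp(-(logit - 1.959963984540054 * se)))
        hi = 1 / (1 + np.exp(-(logit + 1.959963984540054 * se)))
    else:
        lo, hi = proportion_confint(n_dead, n, alpha=0.05, method="jeffreys")
    return p, float(lo), float(hi)


def size_class_rates(
    trees: pd.DataFrame,
    mode: str,
    n_bins: int = 10,
    area_ha: float | None = None,
    interval_years: float = 9.0,
    params: AllometryParams | None = None,
) -> pd.DataFrame:
    """Per-size-class demography and biomass accounting.

    ``trees`` is a matched-tree table with AGB columns (see
    :func:`append_agb_columns`); only fate-classified trees (survived or
    dead) enter.  Mortality per bin is the saturated-binomial proportion
    with a logit-scale CI.  Gains are survivors' biomass changes, losses the
    dead trees' (negative), net their sum; with ``area_ha`` these become
    Mg/ha per decade.  Empty bins are kept and flagged.
    """
    params = params or AllometryParams()
    t = trees[trees["status"].isin([STATUS_SURVIVED, STATUS_DEAD])].copy()
    if "size_t1_m2" not in t.columns:
        raise ValueError("run append_agb_columns first")
    bins = bin_trees(t["size_t1_m2"].to_numpy(), mode, n_bins)
    t["size_bin"] = bins
    edges = bin_edges(t["size_t1_m2"].to_numpy(), mode, n_bins)
    denom_ha = area_ha if area_ha is not None else 1.0
    total_agb = t["agb_t1_kg"].sum()
    scale = 10.0 / interval_years

    rows = []
    for b in range(n_bins):
        g = t[t["size_bin"] == b]
        n = len(g)
        if n == 0:
            rows.append(dict(size_bin=b, mode=mode, n_trees=0, empty=True,
                             edge_lo_m2=edges[b], edge_hi_m2=edges[b + 1]))
            continue
        surv = g[g["status"] == STATUS_SURVIVED]
        n_dead = int((g["status"] == STATUS_DEAD).sum())
        dh, dh_lo, dh_hi = _mean_ci(surv["dh_decade"].to_numpy())
        da, da_lo, da_hi = _mean_ci(surv["da_decade"].to_numpy())
        p, p_lo, p_hi = _mortality_ci(n_dead, n)
        gains = surv["dagb_decade_kg"].sum() / 1000.0 / denom_ha
        losses = g.loc[g["status"] == STATUS_DEAD, "dagb_decade_kg"].sum() / 1000.0 / denom_ha
        rep_size = float(np.sqrt(edges[b] * edges[b + 1]))
        rows.append(
            dict(
                size_bin=b,
                mode=mode,
                n_trees=n,
                empty=False,
                edge_lo_m2=edges[b],
                edge_hi_m2=edges[b + 1],
                mean_dh_decade=dh, dh_ci_lo=dh_lo, dh_ci_hi=dh_hi,
                mean_da_decade=da, da_ci_lo=da_lo, da_ci_hi=da_hi,
                mortality_prob_interval=p,
                mortality_ci_lo=p_lo, mortality_ci_hi=p_hi,
                mortality_pct_decade=100.0 * p * scale,
                agb_stock_mg_ha=g["agb_t1_kg"].sum() / 1000.0 / denom_ha,
                stock_fraction_pct=100.0 * g["agb_t1_kg"].sum() / total_agb,
                gains_mg_ha_decade=gains,
                losses_mg_ha_decade=losses,
                net_mg_ha_decade=gains + losses,
                representative_dbh_cm=float(
                    params.dbh_coef * rep_size**params.dbh_exp * params.cf_dbh
                ),
            )
        )
    return pd.DataFrame(rows)


def demographic_summary(
    trees: pd.DataFrame,
    area_ha: float,
    interval_years: float = 9.0,
    params: AllometryParams | None = None,
) -> dict:
    """Whole-population biomass accounting from a matched-tree table.

    Returns mean first-survey AGB stock (Mg/ha), total gains, losses and net
    change (Mg/ha per decade), and the stock share of the largest percentile
    size class.
    """
    params = params or AllometryParams()
    t = trees[trees["status"].isin([STATUS_SURVIVED, STATUS_DEAD])]
    per = size_class_rates(t, "percentile", 10, area_ha=area_ha,
                           interval_years=interval_years, params=params)
    return {
        "n_trees": int(len(t)),
        "agb_stock_mg_ha": float(t["agb_t1_kg"].sum() / 1000.0 / area_ha),
        "gains_mg_ha_decade": float(per["gains_mg_ha_decade"].sum()),
        "losses_mg_ha_decade": float(per["losses_mg_ha_decade"].sum()),
        "net_mg_ha_decade": float(per["net_mg_ha_decade"].sum()),
        "top_decile_stock_share_pct": float(per.loc[per["size_bin"] == 9, "stock_fraction_pct"].iloc[0]),
    }
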