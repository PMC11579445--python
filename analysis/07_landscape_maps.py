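"""Aggregate tree demography and canopy structure to the 1-ha grid and ask
how well canopy-level change tracks tree-level biomass dynamics.

Per hectare: mean survivor height growth and crown expansion, mortality,
net biomass change, plus two crown-free metrics computed straight from the
CHMs - change in canopy cover above 4 m (% per decade) and change in canopy
volume (m3 per decade).  Correlations among the maps are reported with both
Pearson and Spearman coefficients.
"""

import numpy as np
import pandas as pd
from scipy import stats

import crowntrack as ct

from common import RESULTS, STUDY_CONFIG, ensure_dirs, load_scene


def _plot_maps(cells, grid):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from common import SCRATCH

    fields = [
        ("mean_dh_decade", "height change (m/decade)"),
        ("mortality_pct_decade", "mortality (%/decade)"),
        ("net_dagb_mg_decade", "net AGB change (Mg/decade)"),
        ("d_vol_m3_decade", "canopy volume change (m3/decade)"),
    ]
    fig, axes = plt.subplots(1, len(fields), figsize=(4 * len(fields), 3.6), constrained_layout=True)
    for ax, (col, label) in zip(axes, fields):
        img = np.full((grid.n_cell_rows, grid.n_cell_cols), np.nan)
        for _, row in cells.iterrows():
            img[int(row["cell_row"]), int(row["cell_col"])] = row[col]
        im = ax.imshow(img, cmap="RdYlGn")
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(label, fontsize=9)
        ax.set_xticks([]), ax.set_yticks([])
    SCRATCH.mkdir(exist_ok=True)
    fig.savefig(SCRATCH / "hectare_maps.png", dpi=130)
    plt.close(fig)


def main():
    ensure_dirs()
    _, rasters = load_scene()
    chm1, chm2 = rasters["chm_t1"], rasters["chm_t2"]
    grid = ct.HectareGrid.for_raster(chm1)
    interval = STUDY_CONFIG.interval_years

    canopy = ct.delta_metrics(chm1, chm2, grid, interval)
    trees = pd.read_csv(RESULTS / "matched_trees.csv")
    tree_map = ct.aggregate_tree_rates(trees, grid, interval)

    cells = canopy.merge(tree_map, on=["cell_row", "cell_col"], how="left")
    cells.to_csv(RESULTS / "hectare_maps.csv", index=False)
    from common import SCRATCH

    for col in ("d_vol_m3_decade", "net_dagb_mg_decade"):
        ct.write_raster(ct.cell_table_to_raster(cells, grid, col), SCRATCH / f"{col}_100m.tif")

    print(f"{len(cells)} 1-ha cells; canopy cover {canopy['cover_t1_pct'].mean():.1f}% -> "
          f"{canopy['cover_t2_pct'].mean():.1f}%, "
          f"canopy volume {canopy['volume_t1_m3'].mean():.0f} -> {canopy['volume_t2_m3'].mean():.0f} m3/ha")

    _plot_maps(cells, grid)

    pairs = [
        ("mean_dh_decade", "mean_da_decade"),
        ("mortality_pct_decade", "mean_dh_decade"),
        ("mortality_pct_decade", "mean_da_decade"),
        ("net_dagb_mg_decade", "d_cover_pct_decade"),
        ("net_dagb_mg_decade", "d_vol_m3_decade"),
    ]
    rows = []
    for a, b in pairs:
        d = cells[[a, b]].dropna()
        pear = stats.pearsonr(d[a], d[b])
        spear = stats.spearmanr(d[a], d[b])
        rows.append(dict(var_a=a, var_b=b, n=len(d),
                         pearson=pear.statistic, spearman=spear.statistic))
        print(f"  {a} vs {b}: Pearson {pear.statistic:+.2f}, Spearman {spear.statistic:+.2f}")
    pd.DataFrame(rows).to_csv(RESULTS / "rate_map_correlations.csv", index=False)


if __name__ == "__main__":
    main()
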