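"""Size-resolved demography and biomass accounting.

Trees are placed into ten equal-width bins of log(H x CD) for the rate
curves (height growth, crown expansion, mortality with 95% CIs) and into
ten percentile bins for partitioning biomass stocks, gains, losses and net
change.  Gains + losses must equal net in every bin and overall.
"""

import json

import numpy as np

import pandas as pd

import crowntrack as ct

from common import RESULTS, STUDY_CONFIG, ensure_dirs


def _plot_rates(log_rates):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from common import SCRATCH

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), constrained_layout=True)
    x = np.sqrt(log_rates["edge_lo_m2"] * log_rates["edge_hi_m2"])
    panels = [
        ("mean_dh_decade", "dh_ci_lo", "dh_ci_hi", "height growth (m/decade)"),
        ("mean_da_decade", "da_ci_lo", "da_ci_hi", "crown expansion (m2/decade)"),
    ]
    for ax, (m, lo, hi, label) in zip(axes, panels):
        ax.errorbar(x, log_rates[m], yerr=[log_rates[m] - log_rates[lo], log_rates[hi] - log_rates[m]], fmt="o-")
        ax.set_xscale("log")
        ax.set_xlabel("tree size H x CD (m2)")
        ax.set_ylabel(label)
    ax = axes[2]
    # Jeffreys intervals in zero-death bins need not bracket the point estimate
    lo_err = ((log_rates["mortality_prob_interval"] - log_rates["mortality_ci_lo"]) * 100 * 10 / 9).clip(lower=0)
    hi_err = ((log_rates["mortality_ci_hi"] - log_rates["mortality_prob_interval"]) * 100 * 10 / 9).clip(lower=0)
    ax.errorbar(x, log_rates["mortality_pct_decade"], yerr=[lo_err, hi_err], fmt="o-", color="brown")
    ax.set_xscale("log")
    ax.set_xlabel("tree size H x CD (m2)")
    ax.set_ylabel("mortality (% per decade)")
    SCRATCH.mkdir(exist_ok=True)
    fig.savefig(SCRATCH / "size_class_rates.png", dpi=130)
    plt.close(fig)


def main():
    ensure_dirs()
    trees = pd.read_csv(RESULTS / "matched_trees.csv")
    area_ha = STUDY_CONFIG.extent_m[0] * STUDY_CONFIG.extent_m[1] / 1e4
    interval = STUDY_CONFIG.interval_years

    tables = []
    for mode in ("log_equal_width", "percentile"):
        rates = ct.size_class_rates(trees, mode, 10, area_ha=area_ha, interval_years=interval)
        tables.append(rates)
    all_rates = pd.concat(tables, ignore_index=True)
    all_rates.to_csv(RESULTS / "size_class_rates.csv", index=False)

    log_rates = tables[0][~tables[0]["empty"]]
    print("height growth by size class (m/decade):",
          " ".join(f"{v:.2f}" for v in log_rates["mean_dh_decade"]))
    print("crown expansion by size class (m2/decade):",
          " ".join(f"{v:.1f}" for v in log_rates["mean_da_decade"]))
    print("mortality by size class (% per decade):",
          " ".join(f"{v:.1f}" for v in log_rates["mortality_pct_decade"]))

    _plot_rates(log_rates)

    summary = ct.demographic_summary(trees, area_ha=area_ha, interval_years=interval)
    print(f"AGB stock {summary['agb_stock_mg_ha']:.1f} Mg/ha; "
          f"gains {summary['gains_mg_ha_decade']:+.2f}, losses {summary['losses_mg_ha_decade']:+.2f}, "
          f"net {summary['net_mg_ha_decade']:+.2f} Mg/ha/decade; "
          f"top decile holds {summary['top_decile_stock_share_pct']:.1f}% of stock")
    with open(RESULTS / "biomass_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
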