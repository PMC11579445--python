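"""Generate the synthetic study scene: terrain with a drainage channel,
a hard-core woodland of single-stemmed trees, two canopy height models nine
years apart, and per-survey pulse-density fields.

Writes the ground-truth tree table to results/scene_truth.csv and the
rasters to scratch/ for the downstream scripts.
"""

import numpy as np

from common import RESULTS, STUDY_CONFIG, load_scene


def main():
    truth, rasters = load_scene()
    t = truth.trees
    area_ha = STUDY_CONFIG.extent_m[0] * STUDY_CONFIG.extent_m[1] / 1e4
    print(f"scene: {area_ha:.0f} ha, {len(t)} trees ({len(t) / area_ha:.1f} per ha)")
    print(f"heights {t['H_t1'].min():.1f}-{t['H_t1'].max():.1f} m, mean {t['H_t1'].mean():.1f} m")
    areas = np.pi * t["crown_radius_t1"] ** 2
    print(f"crown areas {areas.min():.1f}-{areas.max():.1f} m2, mean {areas.mean():.1f} m2")
    print(f"deaths over {STUDY_CONFIG.interval_years:.0f} yr: {t['died'].sum()} "
          f"({100 * t['died'].mean():.1f}%), of which dieback {t['dieback'].sum()}")
    print(f"CHM range t1: 0-{rasters['chm_t1'].values.max():.1f} m; "
          f"TWI range {rasters['twi'].values.min():.1f}-{rasters['twi'].values.max():.1f}")
    print(f"tables in {RESULTS}/, rasters in scratch/")


if __name__ == "__main__":
    main()
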