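"""Shared settings for the numbered analysis scripts.

The study scene is a 25-ha synthetic open woodland at the observed stem
density (22 trees/ha), surveyed twice nine years apart with realistic CHM
noise.  Rasters are cached under scratch/ (regenerated if missing) so the
scripts can be run independently and in any order; tables go to results/.
"""

from pathlib import Path

import crowntrack as ct

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

SCENE_SEED = 20120501  # first-survey flight date, as a memorable seed

STUDY_CONFIG = ct.SceneConfig(
    extent_m=(500.0, 500.0),
    stem_density_per_ha=22.0,
    min_crown_gap_m=2.0,
    chm_noise_sd_m=0.15,
    rng_seed=SCENE_SEED,
)

SEG_PARAMS = ct.SegmentationParams()

RASTER_NAMES = ("dtm", "twi", "chm_t1", "chm_t2", "pulse_t1", "pulse_t2")


def ensure_dirs():
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)


def load_scene(config=STUDY_CONFIG):
    """Load the cached study scene, generating it on first use."""
    ensure_dirs()
    truth_csv = RESULTS / "scene_truth.csv"
    paths = {n: SCRATCH / f"{n}.tif" for n in RASTER_NAMES}
    if truth_csv.exists() and all(p.exists() for p in paths.values()):
        import pandas as pd

        trees = pd.read_csv(truth_csv)
        truth = ct.SceneTruth(trees, config)
        rasters = {n: ct.read_raster(p) for n, p in paths.items()}
        return truth, rasters
    truth, rasters = ct.generate_scene(config)
    truth.to_csv(truth_csv)
    for n, p in paths.items():
        ct.write_raster(rasters[n], p)
    ct.save_config(config, RESULTS / "scene_config.yaml")
    return truth, rasters
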