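import numpy as np
import pytest

import crowntrack as ct


@pytest.fixture(scope="session")
def small_cfg():
    """A 4-ha, well-separated, noise-free scene config used across tests."""
    return ct.SceneConfig(
        extent_m=(200.0, 200.0),
        rng_seed=11,
        chm_noise_sd_m=0.0,
        min_crown_gap_m=5.0,
        stem_density_per_ha=15.0,
    )


@pytest.fixture(scope="session")
def small_scene(small_cfg):
    return ct.generate_scene(small_cfg)


@pytest.fixture(scope="session")
def seg_params():
    return ct.SegmentationParams()


def make_uniform_chm(height, nrow=200, ncol=200, res=0.5):
    """A flat CHM of the given height on a local grid."""
    t = ct.GridTransform(0.0, nrow * res, res, res)
    return ct.HeightRaster(np.full((nrow, ncol), float(height)), t)


def paraboloid_chm(trees, nrow=200, ncol=200, res=0.5, base_ratio=0.4):
    """Render (x, y, H, R) tuples as paraboloid caps on a zero ground."""
    t = ct.GridTransform(0.0, nrow * res, res, res)
    rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    px, py = t.pixel_center(rows, cols)
    z = np.zeros((nrow, ncol))
    for x0, y0, H, R in trees:
        r2 = (px - x0) ** 2 + (py - y0) ** 2
        cap = H - (H - base_ratio * H) * r2 / (R * R)
        z = np.maximum(z, np.where(r2 <= R * R, cap, 0.0))
    return ct.HeightRaster(z, t)
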