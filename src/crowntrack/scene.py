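"""Synthetic open-woodland scene generator.

Emulates the study system the pipeline targets: a semi-arid, open-canopy
eucalypt woodland surveyed twice by airborne laser scanning ~a decade apart.
A scene consists of a gently tilted terrain model with a drainage channel, a
hard-core point pattern of single-stemmed trees (heights ~4-22 m, crown
diameters following a power-law allometry on height, non-overlapping
crowns), per-survey canopy height models rendered as paraboloid crown caps,
smooth pulse-density fields for each survey, and a ground-truth tree table
recording every growth and death assignment.

Growth (height and crown-area increments) responds to tree size, topographic
wetness and neighbourhood crowding; death is a per-decade logistic in the
same covariates.  A configurable fraction of "died" trees is rendered as
severe crown dieback (shrunk crown) rather than complete disappearance,
since downstream both are one demographic class.

All randomness derives from ``SceneConfig.rng_seed`` through independent
named streams, so a config reproduces its scene bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import yaml
from scipy import ndimage

from .raster import DEFAULT_NODATA, GridTransform, HeightRaster
from .terrain import compute_twi


@dataclass
class CrownAllometry:
    """Crown diameter CD = a * H^b with lognormal scatter (sd on log scale)."""

    a: float = 1.45
    b: float = 0.90
    scatter_sd: float = 0.15


@dataclass
class GrowthModel:
    """Per-decade growth increments as functions of log size, wetness and
    neighbourhood height (effects centred on their scene means).

    Height growth decays with size (fast in small trees, near zero in the
    largest); crown-area growth rises sigmoidally with size.  Units are m and
    m^2 per decade.
    """

    dh_max: float = 0.55           # m/decade for the smallest trees
    dh_decay: float = 0.55         # e-folding per unit log(H*CD)
    dh_ref_logsize: float = 2.5    # log size where dh_max applies
    da_small: float = 7.0          # m^2/decade in small trees
    da_large: float = 16.0         # m^2/decade plateau in large trees
    da_mid_logsize: float = 4.3    # sigmoid midpoint on log(H*CD)
    da_rate: float = 1.5
    twi_effect_dh: float = 0.05    # m/decade per TWI unit
    twi_effect_da: float = 0.8     # m^2/decade per TWI unit
    comp_effect_dh: float = 0.02   # m/decade per m neighbourhood height
    comp_effect_da: float = 0.3
    sd_dh: float = 0.12            # residual sd, m/decade
    sd_da: float = 5.0             # residual sd, m^2/decade


@dataclass
class MortalityModel:
    """Per-decade death/dieback probability, logistic in log size, TWI and
    neighbourhood height (covariates centred on scene means)."""

    intercept: float = -2.09       # logit of ~11% per decade at reference
    size_slope: float = -0.35      # per unit log(H*CD)
    ref_logsize: float = 4.3
    twi_slope: float = -0.15       # wetter -> lower mortality
    comp_slope: float = 0.10       # taller neighbourhoods -> higher mortality


@dataclass
class SceneConfig:
    extent_m: tuple = (500.0, 500.0)
    chm_resolution_m: float = 0.5
    dtm_resolution_m: float = 5.0
    stem_density_per_ha: float = 22.0
    height_range_m: tuple = (4.0, 22.0)
    height_mu_log: float = float(np.log(10.0))
    height_sigma_log: float = 0.35
    crown_allometry: CrownAllometry = field(default_factory=CrownAllometry)
    min_crown_gap_m: float = 2.0
    edge_margin_m: float = 12.0
    interval_years: float = 9.0
    growth_model: GrowthModel = field(default_factory=GrowthModel)
    mortality_model: MortalityModel = field(default_factory=MortalityModel)
    dieback_fraction: float = 0.25   # of died trees, rendered as shrunk crowns
    dieback_shrink: float = 0.5      # crown-radius factor for dieback trees
    crown_base_ratio: float = 0.4    # crown base height as a fraction of H
    chm_noise_sd_m: float = 0.15
    pulse_density_mean: tuple = (21.4, 23.6)  # pulses/m^2 per survey
    pulse_density_noise_sd: float = 1.5
    pulse_density_corr_m: float = 100.0
    # terrain
    tilt_slope: float = 0.004
    channel_amplitude_m: float = 4.0
    channel_width_m: float = 30.0
    microtopo_sd_m: float = 0.25
    microtopo_corr_m: float = 40.0
    base_elevation_m: float = 450.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_density_per_ha <= 0 or self.chm_resolution_m <= 0 or self.dtm_resolution_m <= 0:
            raise ValueError("densities and resolutions must be strictly positive")
        if self.height_range_m[0] <= 0 or self.height_range_m[1] <= self.height_range_m[0]:
            raise ValueError("invalid height range")
        if self.chm_noise_sd_m < 0 or self.pulse_density_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if min(self.pulse_density_mean) <= 0:
            raise ValueError("pulse density means must be positive")
        if not 0 < self.crown_base_ratio < 1:
            raise ValueError("crown base ratio must be in (0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible stream derived from the scene seed."""
        return np.random.default_rng([int(self.rng_seed), int(stream)])


_STREAM_TERRAIN, _STREAM_TREES, _STREAM_FATE, _STREAM_CHM1, _STREAM_CHM2, _STREAM_PD1, _STREAM_PD2 = range(7)


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene: per-tree table + the config."""

    trees: pd.DataFrame
    config: SceneConfig

    def to_csv(self, path) -> None:
        self.trees.to_csv(path, index=False)

    def live_at(self, survey: str) -> pd.DataFrame:
        if survey == "t1":
            return self.trees
        if survey == "t2":
            return self.trees[(~self.trees["died"]) | self.trees["dieback"]]
        raise ValueError("survey must be 't1' or 't2'")


# ---------------------------------------------------------------------------
# terrain


def channel_polyline(config: SceneConfig) -> shapely.LineString:
    """The drainage-channel centreline: a gentle sine across the scene."""
    w, h = config.extent_m
    xs = np.linspace(0.0, w, 64)
    ys = 0.5 * h + 0.18 * h * np.sin(2.0 * np.pi * xs / w * 1.3 + 0.7)
    return shapely.LineString(np.column_stack([xs, ys]))


def generate_dtm(config: SceneConfig) -> HeightRaster:
    """Terrain model: tilted plane, a Gaussian-profile channel incised along a
    curved polyline, and smooth correlated microtopography."""
    w, h = config.extent_m
    res = config.dtm_resolution_m
    ncol, nrow = round(w / res), round(h / res)
    if abs(ncol * res - w) > 1e-9 or abs(nrow * res - h) > 1e-9:
        raise ValueError("extent must be divisible by the DTM resolution")
    if nrow < 3 or ncol < 3:
        raise ValueError("degenerate extent: DTM must be at least 3x3 cells")
    t = GridTransform(0.0, h, res, res)
    rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    x, y = t.pixel_center(rows, cols)
    z = config.base_elevation_m + config.tilt_slope * (x + 0.5 * y)
    if config.channel_amplitude_m > 0:
        line = channel_polyline(config)
        d = shapely.distance(line, shapely.points(x.ravel(), y.ravel())).reshape(x.shape)
        z = z - config.channel_amplitude_m * np.exp(-0.5 * (d / config.channel_width_m) ** 2)
    if config.microtopo_sd_m > 0:
        rng = config.rng(_STREAM_TERRAIN)
        noise = rng.standard_normal((nrow, ncol))
        sigma_px = config.microtopo_corr_m / res
        smooth = ndimage.gaussian_filter(noise, sigma_px, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            z = z + config.microtopo_sd_m * smooth / sd
    return HeightRaster(z.astype(np.float32), t, "local", DEFAULT_NODATA)


# ---------------------------------------------------------------------------
# tree placement and demography


def _sample_heights(rng: np.random.Generator, n: int, config: SceneConfig) -> np.ndarray:
    """Lognormal heights truncated to the configured range (rejection)."""
    lo, hi = config.height_range_m
    out = np.empty(n)
    got = 0
    while got < n:
        draw = rng.lognormal(config.height_mu_log, config.height_sigma_log, size=2 * (n - got) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - got)
        out[got : got + take] = draw[:take]
        got += take
    return out


def place_trees(
    config: SceneConfig,
    dtm: HeightRaster,
    twi: HeightRaster | None = None,
) -> SceneTruth:
    """Place trees by hard-core dart throwing and assign growth and fate.

    Crown discs are non-overlapping: accepted stems are separated by at least
    R_i + R_j + min_crown_gap_m.  Heights come from the truncated lognormal,
    crown radii from the allometry with lognormal scatter.  TWI is sampled at
    each stem from the wetness raster of the supplied terrain (computed here
    unless passed in); neighbourhood crowding is the analytic counterpart of
    the 25-m mean-canopy-height buffer used downstream.  Growth and death are
    then drawn from the configured models.
    """
    rng = config.rng(_STREAM_TREES)
    w, h = config.extent_m
    area_ha = w * h / 1e4
    target = rng.poisson(config.stem_density_per_ha * area_ha)
    margin = config.edge_margin_m
    if w <= 2 * margin or h <= 2 * margin:
        raise ValueError("extent too small for the edge margin")

    heights = _sample_heights(rng, target, config)
    allo = config.crown_allometry
    cd = allo.a * heights**allo.b * np.exp(rng.normal(0.0, allo.scatter_sd, size=target))
    radii = cd / 2.0

    # dart throwing with a coarse spatial hash for the conflict test
    cell = 2 * radii.max() + config.min_crown_gap_m
    nx_b, ny_b = max(1, int(w // cell)), max(1, int(h // cell))
    buckets: dict = {}
    xs = np.empty(target)
    ys = np.empty(target)
    placed = 0
    max_attempts = 60 * target
    attempts = 0
    order = np.arange(target)
    while placed < target and attempts < max_attempts:
        attempts += 1
        i = order[placed]
        px = rng.uniform(margin, w - margin)
        py = rng.uniform(margin, h - margin)
        bx, by = int(px / w * nx_b), int(py / h * ny_b)
        ok = True
        for dbx in (-1, 0, 1):
            for dby in (-1, 0, 1):
                for j in buckets.get((bx + dbx, by + dby), ()):
                    mind = radii[i] + radii[j] + config.min_crown_gap_m
                    if (px - xs[j]) ** 2 + (py - ys[j]) ** 2 < mind * mind:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            xs[placed], ys[placed] = px, py
            buckets.setdefault((bx, by), []).append(placed)
            placed += 1
    if placed < 0.8 * target:
        raise RuntimeError(
            f"hard-core placement infeasible: achieved {placed / area_ha:.1f} trees/ha "
            f"of target {config.stem_density_per_ha:.1f}"
        )
    n = placed
    xs, ys, heights, radii = xs[:n], ys[:n], heights[:n], radii[:n]

    if twi is None:
        twi = compute_twi(dtm)
    twi_true = np.asarray(twi.sample(xs, ys), dtype=float)

    # analytic neighbourhood: mean crown-surface height within a 25-m annulus
    # around each crown (paraboloid cap mean = base + (H - base)/2)
    mean_surface = config.crown_base_ratio * heights + 0.5 * (1 - config.crown_base_ratio) * heights
    crown_vol_proxy = np.pi * radii**2 * mean_surface
    neigh = np.zeros(n)
    buffer_m = 25.0
    from scipy.spatial import cKDTree

    tree_index = cKDTree(np.column_stack([xs, ys]))
    reach = buffer_m + radii.max() + radii
    for i in range(n):
        js = tree_index.query_ball_point([xs[i], ys[i]], r=reach[i])
        annulus = np.pi * ((radii[i] + buffer_m) ** 2 - radii[i] ** 2)
        total = sum(crown_vol_proxy[j] for j in js if j != i)
        neigh[i] = total / annulus

    fate_rng = config.rng(_STREAM_FATE)
    gm, mm = config.growth_model, config.mortality_model
    logsize = np.log(heights * 2 * radii)
    twi_c = twi_true - twi_true.mean()
    neigh_c = neigh - neigh.mean()

    dh_decade = (
        gm.dh_max * np.exp(-gm.dh_decay * (logsize - gm.dh_ref_logsize))
        + gm.twi_effect_dh * twi_c
        + gm.comp_effect_dh * neigh_c
        + fate_rng.normal(0.0, gm.sd_dh, size=n)
    )
    da_decade = (
        gm.da_small
        + (gm.da_large - gm.da_small) / (1.0 + np.exp(-gm.da_rate * (logsize - gm.da_mid_logsize)))
        + gm.twi_effect_da * twi_c
        + gm.comp_effect_da * neigh_c
        + fate_rng.normal(0.0, gm.sd_da, size=n)
    )

    logit = (
        mm.intercept
        + mm.size_slope * (logsize - mm.ref_logsize)
        + mm.twi_slope * twi_c
        + mm.comp_slope * neigh_c
    )
    p_decade = 1.0 / (1.0 + np.exp(-logit))
    p_interval = 1.0 - (1.0 - p_decade) ** (config.interval_years / 10.0)
    died = fate_rng.uniform(size=n) < p_interval
    dieback = died & (fate_rng.uniform(size=n) < config.dieback_fraction)

    scale = config.interval_years / 10.0
    h2 = np.where(died, 0.0, np.maximum(heights + dh_decade * scale, 0.5))
    a1 = np.pi * radii**2
    a2 = np.maximum(a1 + da_decade * scale, 1.0)
    r2 = np.where(died, 0.0, np.sqrt(a2 / np.pi))
    # dieback trees persist in the second survey with a shrunk crown
    h2 = np.where(dieback, heights, h2)
    r2 = np.where(dieback, radii * config.dieback_shrink, r2)

    trees = pd.DataFrame(
        dict(
            tree_id=np.arange(n),
            x=xs,
            y=ys,
            H_t1=heights,
            crown_radius_t1=radii,
            H_t2=h2,
            crown_radius_t2=r2,
            died=died,
            dieback=dieback,
            TWI_true=twi_true,
            neighbourhood_true=neigh,
            dh_decade_true=np.where(died, np.nan, dh_decade),
            da_decade_true=np.where(died, np.nan, da_decade),
            p_death_decade_true=p_decade,
        )
    )
    return SceneTruth(trees, config)


# ---------------------------------------------------------------------------
# rendering


def render_chm(truth: SceneTruth, which_survey: str, config: SceneConfig | None = None) -> HeightRaster:
    """Rasterise the scene's live crowns onto a zero ground.

    Each crown is a solid-of-revolution paraboloid cap,
    ``z(r) = H - (H - H_base) * (r/R)^2`` with ``H_base = crown_base_ratio*H``;
    a pixel takes the max over overlapping crowns.  Additive Gaussian noise
    (``chm_noise_sd_m``) is applied and the result clipped at 0.  Trees that
    died outright are absent from the second survey; dieback trees appear
    with their shrunk crowns.
    """
    config = config or truth.config
    if which_survey not in ("t1", "t2"):
        raise ValueError("survey must be 't1' or 't2'")
    w, h = config.extent_m
    res = config.chm_resolution_m
    ncol, nrow = round(w / res), round(h / res)
    t = GridTransform(0.0, h, res, res)
    z = np.zeros((nrow, ncol), dtype=np.float64)

    live = truth.live_at(which_survey)
    hcol = "H_t1" if which_survey == "t1" else "H_t2"
    rcol = "crown_radius_t1" if which_survey == "t1" else "crown_radius_t2"
    for x0, y0, H, R in zip(live["x"], live["y"], live[hcol], live[rcol]):
        if R <= 0 or H <= 0:
            continue
        c0 = max(0, int((x0 - R) / res))
        c1 = min(ncol, int(np.ceil((x0 + R) / res)) + 1)
        r0 = max(0, int((h - (y0 + R)) / res))
        r1 = min(nrow, int(np.ceil((h - (y0 - R)) / res)) + 1)
        if r1 <= r0 or c1 <= c0:
            continue
        rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        px, py = t.pixel_center(rows, cols)
        rr2 = (px - x0) ** 2 + (py - y0) ** 2
        inside = rr2 <= R * R
        hb = config.crown_base_ratio * H
        cap = H - (H - hb) * rr2 / (R * R)
        block = z[r0:r1, c0:c1]
        np.maximum(block, np.where(inside, cap, 0.0), out=block)

    if config.chm_noise_sd_m > 0:
        stream = _STREAM_CHM1 if which_survey == "t1" else _STREAM_CHM2
        rng = config.rng(stream)
        z = z + rng.normal(0.0, config.chm_noise_sd_m, size=z.shape)
        np.clip(z, 0.0, None, out=z)
    return HeightRaster(z.astype(np.float32), t, "local", DEFAULT_NODATA)


def render_pulse_density(config: SceneConfig, which_survey: str) -> HeightRaster:
    """Smooth positive pulse-density field (pulses/m^2) around the survey mean,
    on the terrain grid."""
    if which_survey not in ("t1", "t2"):
        raise ValueError("survey must be 't1' or 't2'")
    mean = config.pulse_density_mean[0 if which_survey == "t1" else 1]
    if mean <= 0:
        raise ValueError("pulse density mean must be positive")
    w, h = config.extent_m
    res = config.dtm_resolution_m
    ncol, nrow = round(w / res), round(h / res)
    t = GridTransform(0.0, h, res, res)
    field_vals = np.full((nrow, ncol), mean)
    if config.pulse_density_noise_sd > 0:
        stream = _STREAM_PD1 if which_survey == "t1" else _STREAM_PD2
        rng = config.rng(stream)
        noise = rng.standard_normal((nrow, ncol))
        smooth = ndimage.gaussian_filter(noise, config.pulse_density_corr_m / res, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            # centre the field so its spatial mean is exactly the survey mean
            field_vals = field_vals + config.pulse_density_noise_sd * (smooth - smooth.mean()) / sd
        field_vals = np.maximum(field_vals, 0.1)
    return HeightRaster(field_vals.astype(np.float32), t, "local", DEFAULT_NODATA)


def generate_scene(config: SceneConfig):
    """Convenience wrapper: terrain, wetness, trees, both CHMs, both pulse
    fields.  Returns (truth, dict of rasters)."""
    dtm = generate_dtm(config)
    twi = compute_twi(dtm)
    truth = place_trees(config, dtm, twi=twi)
    rasters = {
        "dtm": dtm,
        "twi": twi,
        "chm_t1": render_chm(truth, "t1", config),
        "chm_t2": render_chm(truth, "t2", config),
        "pulse_t1": render_pulse_density(config, "t1"),
        "pulse_t2": render_pulse_density(config, "t2"),
    }
    return truth, rasters


def truth_crowns(truth: SceneTruth, survey: str) -> list:
    """Ground-truth crowns as circular reference polygons for benchmarking.

    Only trees that would qualify for delineation (taller than 4 m, crown
    area > 9 m^2) are returned.
    """
    from .segmentation import CrownRecord

    live = truth.live_at(survey)
    hcol = "H_t1" if survey == "t1" else "H_t2"
    rcol = "crown_radius_t1" if survey == "t1" else "crown_radius_t2"
    out = []
    for _, row in live.iterrows():
        H, R = row[hcol], row[rcol]
        if H > 4.0 and np.pi * R * R > 9.0:
            poly = shapely.Point(row["x"], row["y"]).buffer(R, quad_segs=32)
            out.append(
                CrownRecord(int(row["tree_id"]), survey, poly, (row["x"], row["y"]), float(H), float(poly.area))
            )
    return out


# ---------------------------------------------------------------------------
# config serialisation (flat YAML)


def _flatten(prefix: str, obj, out: dict) -> None:
    for f in dataclasses.fields(obj):
        val = getattr(obj, f.name)
        key = f"{prefix}{f.name}"
        if dataclasses.is_dataclass(val):
            _flatten(key + ".", val, out)
        elif isinstance(val, tuple):
            out[key] = list(val)
        elif isinstance(val, (np.floating, np.integer)):
            out[key] = val.item()
        else:
            out[key] = val


def save_config(config: SceneConfig, path) -> None:
    """Write the config as a flat key/value YAML file (dotted keys for the
    nested growth/mortality/allometry blocks)."""
    flat: dict = {}
    _flatten("", config, flat)
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)


def load_config(path) -> SceneConfig:
    with open(path) as fh:
        flat = yaml.safe_load(fh)
    nested: dict = {"crown_allometry": {}, "growth_model": {}, "mortality_model": {}}
    kwargs: dict = {}
    for key, val in flat.items():
        if isinstance(val, list):
            val = tuple(val)
        if "." in key:
            group, name = key.split(".", 1)
            nested[group][name] = val
        else:
            kwargs[key] = val
    kwargs["crown_allometry"] = CrownAllometry(**nested["crown_allometry"])
    kwargs["growth_model"] = GrowthModel(**nested["growth_model"])
    kwargs["mortality_model"] = MortalityModel(**nested["mortality_model"])
    return SceneConfig(**kwargs)
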