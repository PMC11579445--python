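# crowntrack

Individual-tree demography from repeat airborne laser scanning (ALS).

Open-canopy woodlands — like the semi-arid, old-growth eucalypt stands of
Western Australia's Great Western Woodlands — are dominated by sparse,
large, single-stemmed trees whose crowns are clearly separable in a
high-resolution canopy height model (CHM). When two ALS surveys a decade
apart are available, every canopy tree can be delineated, re-identified and
measured twice, turning a pair of rasters into a landscape-scale demographic
census: height growth, crown expansion, mortality and crown dieback, and
their consequences for aboveground biomass. `crowntrack` implements that
pipeline end to end for ecologists working with repeat ALS CHMs, together
with a synthetic woodland-scene generator so every stage can be exercised
and validated without survey data.

## What it does

1. **Synthetic scenes** (`crowntrack.scene`) — a terrain model with a
   drainage channel, a hard-core point pattern of trees obeying a
   crown-diameter/height allometry (CD = a·H^b with lognormal scatter),
   TWI- and size-dependent growth and death over the census interval, and
   paraboloid-crown CHM rendering with survey noise and per-survey
   pulse-density fields. Same seed ⇒ bit-identical scene.
2. **Crown segmentation** (`crowntrack.segmentation`) — local-maxima seeding
   with allometric, height-dependent search windows and deterministic
   region growing, run in two stages: a broad window first so large crowns
   are not split, then a small window over the masked remainder to pick up
   small trees. Benchmarking against reference crowns reports correct /
   oversegmented / omitted percentages, mean IoU, precision, recall and F1
   (a crown is correct when IoU > 50%).
3. **Matching and fates** (`crowntrack.matching`) — a first-survey crown
   matches a second-survey crown containing its centroid; crowns involved in
   multi-centroid containment are excluded as ambiguous. Trees losing
   ≥ 30% of height and/or crown area (matched, or unmatched with a collapsed
   in-polygon CHM maximum) are classed as dead or severely died back.
   Survivor increments are scaled to m (and m²) per decade.
4. **Allometry and biomass** (`crowntrack.allometry`) —
   DBH = 0.519·(H·CD)^0.890·CF and AGB = 0.133·DBH^2.375·CF convert crown
   dimensions to stem diameter (cm) and biomass (kg); dead trees lose all
   biomass. Size classes (10 equal-width bins of log H·CD, or deciles)
   carry growth means with 95% CIs, mortality probabilities, and biomass
   stocks/gains/losses/net per hectare.
5. **Covariates** (`crowntrack.terrain`) — topographic wetness index
   ln(a/tan β) from the sink-filled DTM with multiple-flow-direction
   routing; mean CHM height in a 25-m buffer around each crown as a
   competition proxy; pulse-density difference between surveys.
6. **Driver models** (`crowntrack.gam`) — penalized-spline GAMs (REML
   smoothing) with a smooth in log tree size and standardized linear terms;
   Gaussian for growth, binomial-logit for mortality; conditional
   prediction curves and a permutation-envelope Moran's I correlogram for
   residual spatial autocorrelation.
7. **Landscape maps** (`crowntrack.raster`) — 1-ha aggregation of tree
   rates and of two crown-free canopy metrics: Δcover (% of pixels above
   4 m, per decade) and Δvol (pixel height × area summed, per decade; +1 m
   mean height ≡ +10 000 m³ per hectare).

## Worked example

```python
import crowntrack as ct

cfg = ct.SceneConfig(extent_m=(500.0, 500.0), rng_seed=20120501,
                     chm_noise_sd_m=0.15)
truth, rasters = ct.generate_scene(cfg)
out = ct.demography_table(rasters["chm_t1"], rasters["chm_t2"],
                          ct.SegmentationParams(), cfg.interval_years,
                          twi=rasters["twi"],
                          pulse_t1=rasters["pulse_t1"],
                          pulse_t2=rasters["pulse_t2"])
trees = out["trees"]
surv = trees[trees.status == "survived"]
print(len(trees), "crowns;",
      (trees.status == "dead_or_dieback").sum(), "died;",
      f"growth {surv.dh_decade.mean():+.2f} m/decade,",
      f"{surv.da_decade.mean():+.1f} m2/decade")
```

prints

```
580 crowns; 49 died; growth +0.19 m/decade, +11.0 m2/decade
```

i.e. on this 25-ha synthetic scene the pipeline tracked 580 canopy trees,
classed 49 as dead or died-back over the 9-yr interval (≈ 9.4% per decade
under linear scaling), and measured survivors growing ~0.19 m per decade in
height while expanding their crowns by ~11 m² per decade — against a scene
ground truth it matches at 100% for fate classification.

The numbered scripts under `analysis/` run the full study sequence
(simulate → segment → match → covariates → size structure → driver models
→ landscape maps), printing what each stage finds and writing tables under
`results/` (large rasters go to `scratch/`).

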