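"""Raster I/O, alignment and the 1-ha canopy metrics."""

import numpy as np
import pandas as pd
import pytest

import crowntrack as ct
from crowntrack.raster import AlignmentReport

from conftest import make_uniform_chm


def _raster(values, res=0.5, x0=0.0, y0=None):
    values = np.asarray(values)
    y0 = y0 if y0 is not None else values.shape[0] * res
    return ct.HeightRaster(values, ct.GridTransform(x0, y0, res, res))


class TestGeoTiffRoundTrip:
    def test_values_transform_nodata_preserved(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 20, (10, 10)).astype(np.float32)
        vals[2, 3] = -9999.0
        r = ct.HeightRaster(vals, ct.GridTransform(1000.0, 2000.0, 0.5, 0.5), crs="EPSG:28351")
        path = tmp_path / "r.tif"
        ct.write_raster(r, path)
        back = ct.read_raster(path)
        np.testing.assert_array_equal(back.values, vals)
        assert back.transform == r.transform
        assert back.nodata == r.nodata
        assert back.crs == "EPSG:28351"
        assert not back.valid_mask()[2, 3]

    def test_missing_file_mentions_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.tif"):
            ct.read_raster(tmp_path / "nope.tif")

    def test_plain_tiff_without_geotags_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "plain.tif", np.zeros((4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="georeferencing"):
            ct.read_raster(tmp_path / "plain.tif")


class TestAlignment:
    def test_identical_grids_full_overlap(self):
        a = _raster(np.zeros((20, 20)))
        rep = ct.check_alignment(a, a.copy())
        assert rep.compatible and rep.overlap_shape == (20, 20)

    def test_integer_pixel_shift_compatible(self):
        a = _raster(np.zeros((20, 20)))
        b = ct.HeightRaster(np.zeros((20, 20)), ct.GridTransform(1.0, 10.0, 0.5, 0.5))
        rep = ct.check_alignment(a, b)
        assert rep.compatible
        assert rep.overlap_shape == (20, 18)
        ca, cb = ct.clip_to_common(a, b)
        assert ca.shape == cb.shape == (20, 18)
        assert ca.transform == cb.transform

    def test_incompatible_resolution_raises(self):
        a = _raster(np.zeros((20, 20)), res=0.5)
        b = _raster(np.zeros((10, 10)), res=1.0)
        with pytest.raises(ValueError, match="resolution"):
            ct.check_alignment(a, b)

    def test_disjoint_extents_raise(self):
        a = _raster(np.zeros((10, 10)))
        b = ct.HeightRaster(np.zeros((10, 10)), ct.GridTransform(100.0, 5.0, 0.5, 0.5))
        with pytest.raises(ValueError, match="overlap"):
            ct.check_alignment(a, b)


class TestCanopyCover:
    def test_uniform_above_threshold(self):
        chm = make_uniform_chm(5.0)
        grid = ct.HectareGrid.for_raster(chm)
        cover = ct.canopy_cover(chm, grid)
        assert (cover["cover_pct"] == 100.0).all()

    def test_half_above(self):
        vals = np.full((200, 200), 3.0)
        vals[:, :100] = 5.0
        cover = ct.canopy_cover(_raster(vals), ct.HectareGrid.for_raster(_raster(vals)))
        assert cover["cover_pct"].iloc[0] == 50.0

    def test_exactly_at_threshold_is_not_cover(self):
        chm = make_uniform_chm(4.0)
        cover = ct.canopy_cover(chm, ct.HectareGrid.for_raster(chm))
        assert (cover["cover_pct"] == 0.0).all()

    def test_all_nodata_cell_flagged_not_zero(self):
        vals = np.full((200, 200), -9999.0)
        chm = _raster(vals)
        cover = ct.canopy_cover(chm, ct.HectareGrid.for_raster(chm))
        assert cover["all_nodata"].all()
        assert cover["cover_pct"].isna().all()


class TestCanopyVolume:
    def test_uniform_hectare(self):
        chm = make_uniform_chm(10.0)  # exactly 1 ha at 0.5-m pixels
        vol = ct.canopy_volume(chm, ct.HectareGrid.for_raster(chm))
        assert vol["volume_m3"].iloc[0] == pytest.approx(100_000.0)

    def test_one_metre_gain_is_ten_thousand_m3(self):
        chm1 = make_uniform_chm(10.0)
        chm2 = make_uniform_chm(11.0)
        grid = ct.HectareGrid.for_raster(chm1)
        v1 = ct.canopy_volume(chm1, grid)["volume_m3"].iloc[0]
        v2 = ct.canopy_volume(chm2, grid)["volume_m3"].iloc[0]
        assert v2 - v1 == pytest.approx(10_000.0)

    def test_zero_chm(self):
        chm = make_uniform_chm(0.0)
        assert ct.canopy_volume(chm, ct.HectareGrid.for_raster(chm))["volume_m3"].iloc[0] == 0.0

    def test_linearity(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 15, (200, 200))
        chm = _raster(vals)
        grid = ct.HectareGrid.for_raster(chm)
        v1 = ct.canopy_volume(chm, grid)["volume_m3"]
        v3 = ct.canopy_volume(_raster(3 * vals), grid)["volume_m3"]
        np.testing.assert_allclose(v3, 3 * v1, rtol=1e-12)

    def test_cell_sum_conserves_raster_total(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 15, (420, 380))  # partial edge cells on purpose
        chm = _raster(vals)
        grid = ct.HectareGrid.for_raster(chm)
        total = ct.canopy_volume(chm, grid)["volume_m3"].sum()
        assert total == pytest.approx(vals.sum() * 0.25, rel=1e-12)
        assert ct.canopy_cover(chm, grid)["partial"].any()


class TestDeltaMetrics:
    def test_identical_surveys_zero_change(self):
        chm = make_uniform_chm(8.0)
        grid = ct.HectareGrid.for_raster(chm)
        d = ct.delta_metrics(chm, chm.copy(), grid, 9.0)
        assert (d["d_cover_pct_decade"] == 0).all()
        assert (d["d_vol_m3_decade"] == 0).all()

    def test_per_decade_scaling(self):
        chm1 = make_uniform_chm(10.0)
        chm2 = make_uniform_chm(10.9)
        grid = ct.HectareGrid.for_raster(chm1)
        d = ct.delta_metrics(chm1, chm2, grid, 9.0)
        assert d["d_vol_m3_decade"].iloc[0] == pytest.approx(10_000.0, rel=1e-6)

    def test_cover_change_scaling(self):
        # 24.0% -> 25.9% over 9 yr is ~+2.11% per decade
        vals1 = np.zeros((200, 200))
        vals1.ravel()[: int(40000 * 0.240)] = 5.0
        vals2 = np.zeros((200, 200))
        vals2.ravel()[: int(40000 * 0.259)] = 5.0
        grid = ct.HectareGrid.for_raster(_raster(vals1))
        d = ct.delta_metrics(_raster(vals1), _raster(vals2), grid, 9.0)
        assert d["d_cover_pct_decade"].iloc[0] == pytest.approx((25.9 - 24.0) * 10 / 9, rel=1e-9)

    def test_antisymmetric_under_survey_swap(self):
        rng = np.random.default_rng(3)
        chm1 = _raster(rng.uniform(0, 12, (200, 200)))
        chm2 = _raster(rng.uniform(0, 12, (200, 200)))
        grid = ct.HectareGrid.for_raster(chm1)
        fwd = ct.delta_metrics(chm1, chm2, grid, 9.0)
        rev = ct.delta_metrics(chm2, chm1, grid, 9.0)
        np.testing.assert_allclose(fwd["d_vol_m3_decade"], -rev["d_vol_m3_decade"], rtol=1e-12)
        np.testing.assert_allclose(fwd["d_cover_pct_decade"], -rev["d_cover_pct_decade"], atol=1e-12)

    def test_misaligned_inputs_rejected(self):
        chm1 = make_uniform_chm(10.0)
        chm2 = ct.HeightRaster(np.full((200, 200), 10.0), ct.GridTransform(3.0, 100.0, 0.5, 0.5))
        with pytest.raises(ValueError):
            ct.delta_metrics(chm1, chm2, ct.HectareGrid.for_raster(chm1), 9.0)


class TestHectareRasterExport:
    def test_cell_table_round_trips_through_geotiff(self, tmp_path):
        chm = make_uniform_chm(5.0, 400, 400)
        grid = ct.HectareGrid.for_raster(chm)
        vol = ct.canopy_volume(chm, grid)
        coarse = ct.cell_table_to_raster(vol, grid, "volume_m3")
        assert coarse.shape == (2, 2)
        assert coarse.transform.dx == 100.0
        ct.write_raster(coarse, tmp_path / "vol.tif")
        back = ct.read_raster(tmp_path / "vol.tif")
        np.testing.assert_array_equal(back.values, coarse.values)

    def test_habitat_mask_flags_cells(self):
        chm = make_uniform_chm(5.0, 400, 400)
        mask_vals = np.zeros((400, 400))
        mask_vals[:200, :200] = 1.0  # one masked hectare
        mask = ct.HeightRaster(mask_vals, chm.transform)
        grid = ct.HectareGrid.for_raster(chm, mask_raster=mask)
        cover = ct.canopy_cover(chm, grid)
        assert cover["masked"].sum() == 1
        assert cover.loc[(cover["cell_row"] == 0) & (cover["cell_col"] == 0), "masked"].iloc[0]


class TestTreeRateAggregation:
    def test_basic_cell_rates(self):
        chm = make_uniform_chm(5.0)
        grid = ct.HectareGrid.for_raster(chm)
        trees = pd.DataFrame(
            dict(
                x=[10.0, 20.0, 30.0, 40.0],
                y=[10.0, 20.0, 30.0, 40.0],
                status=["survived", "survived", "dead_or_dieback", "ambiguous_excluded"],
                dh_decade=[0.2, 0.4, np.nan, np.nan],
                da_decade=[10.0, 20.0, np.nan, np.nan],
                dagb_decade_kg=[50.0, 100.0, -300.0, np.nan],
            )
        )
        out = ct.aggregate_tree_rates(trees, grid, 9.0)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mean_dh_decade"] == pytest.approx(0.3)
        assert row["mortality_pct_decade"] == pytest.approx(100.0 / 3 * 10 / 9)
        assert row["net_dagb_mg_decade"] == pytest.approx(-0.150)
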