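"""Crown allometry, biomass accounting and size-class summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import crowntrack as ct


class TestDbh:
    def test_reference_tree(self):
        # independent scalar evaluation: 0.519 * 50**0.890 * 1.002
        expected = 0.519 * math.exp(0.890 * math.log(50.0)) * 1.002
        assert ct.estimate_dbh(10.0, 5.0) == pytest.approx(expected, rel=1e-12)
        assert ct.estimate_dbh(10.0, 5.0) == pytest.approx(16.91, abs=0.01)

    def test_unit_argument(self):
        assert ct.estimate_dbh(1.0, 1.0) == pytest.approx(0.519 * 1.002)

    def test_doubling_scaling(self):
        ratio = ct.estimate_dbh(10.0, 10.0) / ct.estimate_dbh(10.0, 5.0)
        assert ratio == pytest.approx(2**0.890, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ct.estimate_dbh(-1.0, 5.0)


class TestAgb:
    def test_reference_stem(self):
        expected = 0.133 * math.exp(2.375 * math.log(20.0)) * 1.067
        assert ct.estimate_agb(20.0) == pytest.approx(expected, rel=1e-12)
        assert ct.estimate_agb(20.0) == pytest.approx(174.66, abs=0.1)

    def test_unit_stem(self):
        assert ct.estimate_agb(1.0) == pytest.approx(0.133 * 1.067)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        h=st.floats(4.0, 25.0), cd=st.floats(1.0, 25.0),
        dh=st.floats(0.01, 5.0), dcd=st.floats(0.01, 5.0),
    )
    def test_composite_allometry_strictly_increasing(self, h, cd, dh, dcd):
        base = ct.tree_agb(h, cd)
        assert ct.tree_agb(h + dh, cd) > base
        assert ct.tree_agb(h, cd + dcd) > base

    def test_realistic_magnitude(self):
        # a mean-sized tree (10.9 m, 12.6 m crown) carries a DBH in the tens of cm
        dbh = ct.estimate_dbh(10.9, 12.6)
        assert 20 < dbh < 90


class TestBinning:
    def test_log_equal_width_edges(self):
        sizes = np.concatenate([[10.0, 1000.0], np.exp(np.random.default_rng(0).uniform(np.log(10), np.log(1000), 100))])
        bins = ct.bin_trees(sizes, "log_equal_width", 10)
        from crowntrack.allometry import bin_edges

        edges = bin_edges(sizes, "log_equal_width", 10)
        np.testing.assert_allclose(edges[0], 10.0)
        np.testing.assert_allclose(edges[1], 10 ** 1.2, rtol=1e-9)  # first bin [10, 15.85)
        assert bins.min() == 0 and bins.max() == 9
        # max value goes in the last (right-inclusive) bin
        assert bins[1] == 9

    def test_percentile_equal_counts(self):
        rng = np.random.default_rng(1)
        sizes = np.exp(rng.normal(4, 1, 42210))
        bins = ct.bin_trees(sizes, "percentile", 10)
        counts = np.bincount(bins, minlength=10)
        assert (counts == 4221).all()

    def test_degenerate_inputs_error(self):
        ones = np.ones(100)
        with pytest.raises(ValueError):
            ct.bin_trees(ones, "log_equal_width")
        with pytest.raises(ValueError):
            ct.bin_trees(ones, "percentile")

    def test_too_few_trees_error(self):
        with pytest.raises(ValueError):
            ct.bin_trees(np.arange(1, 6, dtype=float), "percentile", 10)


def _synthetic_matched_table(n=2000, seed=0, interval=9.0):
    """A matched-tree table with plausible crowns, growth and deaths."""
    rng = np.random.default_rng(seed)
    h1 = np.exp(rng.normal(np.log(10), 0.3, n)).clip(4.2, 22)
    cd1 = 1.45 * h1**0.9 * np.exp(rng.normal(0, 0.15, n))
    a1 = np.pi * (cd1 / 2) ** 2
    died = rng.uniform(size=n) < 0.1
    h2 = np.where(died, np.nan, h1 + rng.normal(0.2, 0.15, n) * interval / 10)
    a2 = np.where(died, np.nan, a1 + rng.normal(13, 6, n) * interval / 10)
    df = pd.DataFrame(
        dict(
            h_t1=h1, a_t1=a1, h_t2=h2, a_t2=np.clip(a2, 1, None),
            status=np.where(died, ct.STATUS_DEAD, ct.STATUS_SURVIVED),
            dh_decade=(h2 - h1) * 10 / interval,
            da_decade=(a2 - a1) * 10 / interval,
        )
    )
    return ct.append_agb_columns(df, interval)


class TestAgbChange:
    def test_dead_tree_loses_everything(self):
        df = pd.DataFrame(
            dict(h_t1=[10.0], a_t1=[np.pi * 6.25], h_t2=[np.nan], a_t2=[np.nan],
                 status=[ct.STATUS_DEAD], dh_decade=[np.nan], da_decade=[np.nan])
        )
        out = ct.append_agb_columns(df, 9.0)
        assert out["agb_t2_kg"].iloc[0] == 0.0
        assert out["dagb_decade_kg"].iloc[0] == pytest.approx(-out["agb_t1_kg"].iloc[0] * 10 / 9)

    def test_dead_117kg_tree(self):
        # find dimensions giving AGB_t1 = 117 kg, then check the -130 kg/decade loss
        from scipy.optimize import brentq

        h = brentq(lambda hh: ct.tree_agb(hh, 1.45 * hh**0.9) - 117.0, 4, 25)
        cd = 1.45 * h**0.9
        df = pd.DataFrame(
            dict(h_t1=[h], a_t1=[np.pi * (cd / 2) ** 2], h_t2=[np.nan], a_t2=[np.nan],
                 status=[ct.STATUS_DEAD], dh_decade=[np.nan], da_decade=[np.nan])
        )
        out = ct.append_agb_columns(df, 9.0)
        assert out["dagb_decade_kg"].iloc[0] == pytest.approx(-117 * 10 / 9, rel=1e-6)

    def test_unchanged_survivor_zero_change(self):
        df = pd.DataFrame(
            dict(h_t1=[10.0], a_t1=[100.0], h_t2=[10.0], a_t2=[100.0],
                 status=[ct.STATUS_SURVIVED], dh_decade=[0.0], da_decade=[0.0])
        )
        out = ct.append_agb_columns(df, 9.0)
        assert out["dagb_decade_kg"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_excluded_trees_stay_nan(self):
        df = pd.DataFrame(
            dict(h_t1=[10.0], a_t1=[100.0], h_t2=[np.nan], a_t2=[np.nan],
                 status=[ct.STATUS_AMBIGUOUS], dh_decade=[np.nan], da_decade=[np.nan])
        )
        out = ct.append_agb_columns(df, 9.0)
        assert np.isnan(out["dagb_decade_kg"].iloc[0])


class TestSizeClassRates:
    def test_saturated_mortality_is_bin_proportion(self):
        df = _synthetic_matched_table()
        rates = ct.size_class_rates(df, "percentile", 10, interval_years=9.0)
        for _, row in rates.iterrows():
            sel = df[ct.bin_trees(df["size_t1_m2"].to_numpy(), "percentile", 10) == row["size_bin"]]
            assert row["mortality_prob_interval"] == pytest.approx(
                (sel["status"] == ct.STATUS_DEAD).mean()
            )
            assert row["mortality_ci_lo"] <= row["mortality_prob_interval"] <= row["mortality_ci_hi"]

    def test_all_survivor_bin_has_finite_ci(self):
        df = _synthetic_matched_table(n=200, seed=3)
        df["status"] = ct.STATUS_SURVIVED
        df["dagb_decade_kg"] = df["dagb_decade_kg"].fillna(0)
        rates = ct.size_class_rates(df, "percentile", 10, interval_years=9.0)
        assert (rates["mortality_prob_interval"] == 0).all()
        assert (rates["mortality_ci_hi"] > 0).all() and np.isfinite(rates["mortality_ci_hi"]).all()

    def test_gains_plus_losses_equal_net_exactly(self):
        df = _synthetic_matched_table()
        for mode in ("percentile", "log_equal_width"):
            rates = ct.size_class_rates(df, mode, 10, area_ha=25.0, interval_years=9.0)
            np.testing.assert_array_equal(
                rates["net_mg_ha_decade"].to_numpy(),
                (rates["gains_mg_ha_decade"] + rates["losses_mg_ha_decade"]).to_numpy(),
            )

    def test_stock_fractions_sum_to_100(self):
        df = _synthetic_matched_table()
        rates = ct.size_class_rates(df, "percentile", 10, area_ha=25.0, interval_years=9.0)
        assert rates["stock_fraction_pct"].sum() == pytest.approx(100.0, rel=1e-12)

    def test_percentile_stocks_monotone_in_size(self):
        df = _synthetic_matched_table()
        rates = ct.size_class_rates(df, "percentile", 10, area_ha=25.0, interval_years=9.0)
        stocks = rates["agb_stock_mg_ha"].to_numpy()
        assert (np.diff(stocks) > 0).all()

    def test_mean_growth_cis_bracket_means(self):
        df = _synthetic_matched_table()
        rates = ct.size_class_rates(df, "log_equal_width", 10, interval_years=9.0)
        ok = rates[~rates["empty"]]
        assert ((ok["dh_ci_lo"] <= ok["mean_dh_decade"]) & (ok["mean_dh_decade"] <= ok["dh_ci_hi"])).all()


class TestDemographicSummary:
    def test_internal_consistency(self):
        df = _synthetic_matched_table(n=4000, seed=5)
        out = ct.demographic_summary(df, area_ha=100.0, interval_years=9.0)
        assert out["net_mg_ha_decade"] == pytest.approx(
            out["gains_mg_ha_decade"] + out["losses_mg_ha_decade"], rel=1e-12
        )
        assert out["agb_stock_mg_ha"] == pytest.approx(df["agb_t1_kg"].sum() / 1000 / 100.0)
        assert 0 < out["top_decile_stock_share_pct"] < 100
        assert out["gains_mg_ha_decade"] > 0 > out["losses_mg_ha_decade"]

    def test_top_decile_share_dominates_equal_share(self):
        df = _synthetic_matched_table(n=4000, seed=6)
        out = ct.demographic_summary(df, area_ha=100.0)
        assert out["top_decile_stock_share_pct"] > 10.0  # right-skewed sizes
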