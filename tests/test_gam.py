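"""Penalized-spline driver models: recovery, limits, predictions, Moran's I."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import crowntrack as ct
from crowntrack.gam import fit_gam, linear_coefficient, predict_conditional


def simulate_drivers(n=5000, seed=7, beta_twi=0.05, sd=0.12, null=False):
    """Growth data with a smooth size effect and linear covariate effects."""
    rng = np.random.default_rng(seed)
    size = np.exp(rng.uniform(2.3, 6.2, n))
    twi = rng.normal(6, 1.5, n)
    nh = rng.normal(2, 0.8, n)
    pdd = rng.normal(2.2, 0.7, n)
    s = np.log(size)
    f = 0.55 * np.exp(-0.55 * (s - 2.5))
    if null:
        y = rng.normal(0, sd, n)
    else:
        y = f + beta_twi * (twi - 6) + 0.02 * (nh - 2) + rng.normal(0, sd, n)
    return pd.DataFrame(
        dict(dh=y, size=size, twi=twi, neighbourhood_height=nh, pulse_density_diff=pdd)
    ), beta_twi * twi.std()


SPEC = ct.GamSpec(response="dh")


class TestGaussianFit:
    def test_recovers_linear_twi_effect(self):
        df, beta_std = simulate_drivers()
        fit = fit_gam(df, SPEC)
        est, se = linear_coefficient(fit, "twi")
        assert abs(est - beta_std) < 2 * se

    def test_null_model_flat(self):
        df, _ = simulate_drivers(null=True, seed=3)
        fit = fit_gam(df, SPEC)
        for term in ("twi", "neighbourhood_height", "pulse_density_diff"):
            est, se = linear_coefficient(fit, term)
            assert abs(est) < 2.5 * se
        # smooth collapses to its null space (constant + linear): edf ~ 2
        assert fit.edf_smooth < 2.5

    def test_training_predictions_reproduce_fitted(self):
        df, _ = simulate_drivers(n=1000, seed=5)
        fit = fit_gam(df, SPEC)
        pred, extra = fit.predict(
            df["size"].to_numpy(),
            {k: df[k].to_numpy() for k in SPEC.linear},
        )
        np.testing.assert_allclose(pred, fit.fitted, rtol=1e-10)
        assert not extra.any()

    def test_linear_limit_equals_ols(self):
        import statsmodels.api as sm

        df, _ = simulate_drivers(n=800, seed=9)
        fit = fit_gam(df, SPEC, fixed_gamma=1e-12)
        s = np.log(df["size"])
        X = np.column_stack([np.ones(len(df)), s] + [
            (df[k] - df[k].mean()) / df[k].std(ddof=0) for k in SPEC.linear
        ])
        ols = sm.OLS(df["dh"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.fitted, ols.fittedvalues, atol=1e-6)
        # standardized linear coefficients agree with OLS
        for k, name in enumerate(SPEC.linear):
            est, _ = linear_coefficient(fit, name)
            assert est == pytest.approx(ols.params[2 + k], abs=1e-6)

    def test_mean_prediction_matches_mean_response(self):
        df, _ = simulate_drivers(n=3000, seed=11)
        fit = fit_gam(df, SPEC)
        raw = {k: np.full(50, df[k].mean()) for k in SPEC.linear}
        sizes = np.exp(np.linspace(np.log(df["size"].min()), np.log(df["size"].max()), 50))
        pred, _ = fit.predict(sizes, raw)
        # centred penalized fit: average prediction over the size range tracks
        # the size-profile of the mean response; crude but telling check at
        # the centre of mass
        mid = np.full(1, np.exp(np.log(df["size"]).mean()))
        pmid, _ = fit.predict(mid, {k: np.full(1, df[k].mean()) for k in SPEC.linear})
        resp_near_mid = df[np.abs(np.log(df["size"]) - np.log(df["size"]).mean()) < 0.3]["dh"]
        assert abs(pmid[0] - resp_near_mid.mean()) < 0.02 + 3 * resp_near_mid.std() / np.sqrt(len(resp_near_mid))

    def test_constant_covariate_rejected(self):
        df, _ = simulate_drivers(n=300, seed=1)
        df["twi"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            fit_gam(df, SPEC)


class TestBinomialFit:
    def _mortality_data(self, n=5000, seed=13):
        rng = np.random.default_rng(seed)
        size = np.exp(rng.uniform(2.3, 6.2, n))
        twi = rng.normal(6, 1.5, n)
        nh = rng.normal(2, 0.8, n)
        pdd = rng.normal(0, 0.7, n)
        s = np.log(size)
        logit = -2.0 - 0.35 * (s - 4.3) - 0.3 * (twi - 6)
        p = 1 / (1 + np.exp(-logit))
        died = (rng.uniform(size=n) < p).astype(float)
        return pd.DataFrame(
            dict(died=died, size=size, twi=twi, neighbourhood_height=nh, pulse_density_diff=pdd)
        ), p, s

    def test_recovers_generating_curve(self):
        df, p_true, s = self._mortality_data()
        spec = ct.GamSpec(response="died", family="binomial")
        fit = fit_gam(df, spec)
        est, se = linear_coefficient(fit, "twi")
        assert abs(est - (-0.3 * df["twi"].std())) < 3 * se
        # predicted probability at mean covariates across the size range
        # brackets the generating logistic within a simulation-scale band
        grid = np.exp(np.linspace(2.5, 6.0, 20))
        raw = {k: np.full(20, df[k].mean()) for k in spec.linear}
        pred, _ = fit.predict(grid, raw)
        truth = 1 / (1 + np.exp(-(-2.0 - 0.35 * (np.log(grid) - 4.3))))
        assert np.max(np.abs(pred - truth)) < 0.05

    def test_predictions_in_unit_interval(self):
        df, _, _ = self._mortality_data(n=2000, seed=17)
        fit = fit_gam(df, ct.GamSpec(response="died", family="binomial"))
        pc = predict_conditional(fit, "twi", fixed_raw={"pulse_density_diff": 0.0})
        assert ((pc["prediction"] > 0) & (pc["prediction"] < 1)).all()

    def test_monotone_covariate_orders_curves(self):
        df, _, _ = self._mortality_data(n=4000, seed=19)
        fit = fit_gam(df, ct.GamSpec(response="died", family="binomial"))
        pc = predict_conditional(fit, "twi", fixed_raw={"pulse_density_diff": 0.0})
        low = pc[pc["level"] == "low"]["prediction"].to_numpy()
        high = pc[pc["level"] == "high"]["prediction"].to_numpy()
        assert (high < low).all()  # wetter means lower mortality everywhere

    def test_one_class_response_rejected(self):
        df, _, _ = self._mortality_data(n=500, seed=23)
        df["died"] = 0.0
        with pytest.raises(ValueError, match="both 0s and 1s"):
            fit_gam(df, ct.GamSpec(response="died", family="binomial"))


class TestAgainstMgcv:
    def test_gaussian_coefficients_match_mgcv(self, tmp_path):
        df, _ = simulate_drivers(n=1500, seed=21)
        # standardize outside so both fitters see identical columns
        d = pd.DataFrame(
            dict(
                dh=df["dh"],
                size=df["size"],
                twi=(df["twi"] - df["twi"].mean()) / df["twi"].std(ddof=0),
                nh=(df["neighbourhood_height"] - df["neighbourhood_height"].mean())
                / df["neighbourhood_height"].std(ddof=0),
                pdd=(df["pulse_density_diff"] - df["pulse_density_diff"].mean())
                / df["pulse_density_diff"].std(ddof=0),
            )
        )
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            f'd <- read.csv("{csv}")\n'
            "suppressMessages(library(mgcv))\n"
            'm <- gam(dh ~ s(log(size), k=10, bs="ps") + twi + nh + pdd, data=d, method="REML")\n'
            'write.csv(data.frame(term=rownames(summary(m)$p.table), est=summary(m)$p.table[,1], se=summary(m)$p.table[,2]),\n'
            f'          "{tmp_path / "out.csv"}", row.names=FALSE)\n'
        )
        res = subprocess.run(["Rscript", str(rscript)], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(tmp_path / "out.csv").set_index("term")

        spec = ct.GamSpec(response="dh", linear=("twi", "nh", "pdd"))
        fit = fit_gam(d, spec)
        for term in ("twi", "nh", "pdd"):
            est, se = linear_coefficient(fit, term)
            assert est == pytest.approx(ref.loc[term, "est"], abs=2e-4)
            assert se == pytest.approx(ref.loc[term, "se"], rel=0.05)


class TestCorrelogram:
    def test_iid_residuals_inside_envelope(self):
        rng = np.random.default_rng(31)
        n = 300
        x, y = rng.uniform(0, 500, n), rng.uniform(0, 500, n)
        r = rng.normal(0, 1, n)
        cg = ct.residual_spatial_autocorrelation(r, x, y, n_bins=8, seed=1)
        assert cg["inside_envelope"].mean() >= 0.75

    def test_smooth_field_detected_at_short_range(self):
        rng = np.random.default_rng(33)
        n = 400
        x, y = rng.uniform(0, 500, n), rng.uniform(0, 500, n)
        r = np.sin(x / 80.0) + np.cos(y / 80.0) + rng.normal(0, 0.1, n)
        cg = ct.residual_spatial_autocorrelation(r, x, y, n_bins=8, seed=2)
        first = cg.iloc[0]
        assert first["moran_i"] > first["env_hi"]  # significant positive I

    def test_single_bin_equals_global_moran(self):
        rng = np.random.default_rng(35)
        n = 120
        x, y = rng.uniform(0, 100, n), rng.uniform(0, 100, n)
        r = rng.normal(0, 1, n)
        cg = ct.residual_spatial_autocorrelation(r, x, y, n_bins=1, n_permutations=9, seed=3)
        rc = r - r.mean()
        ii, jj = np.triu_indices(n, k=1)
        s0 = 2 * len(ii)
        expected = (n / s0) * 2 * (rc[ii] * rc[jj]).sum() / (rc**2).sum()
        assert cg["moran_i"].iloc[0] == pytest.approx(expected, rel=1e-12)
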