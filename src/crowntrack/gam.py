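"""Generalised additive models for demographic drivers.

Each model has one penalized smooth term in tree size (first-survey
H x CD on the log scale is left to the caller; the smooth is agnostic) and
standardized linear terms for wetness, neighbourhood height and
pulse-density difference.  Gaussian-identity models serve height growth and
crown expansion; the mortality model is binomial-logit.

The smooth is a P-spline: a cubic B-spline basis on equally spaced knots
with a second-order difference penalty.  The penalty's null space (constant
+ linear trend) joins the fixed effects, the range space becomes i.i.d.
random effects, and the smoothing parameter is the variance ratio selected
by exact restricted maximum likelihood (REML) for Gaussian models and by
penalized quasi-likelihood (REML on the working model at each IRLS step)
for the binomial.  Posterior (Bayesian) covariance gives coefficient
standard errors and the smooth's effective degrees of freedom, following
the usual penalized-regression conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar


@dataclass
class GamSpec:
    response: str
    family: str = "gaussian"          # "gaussian" | "binomial"
    smooth: str = "size"              # column with the smooth covariate
    linear: tuple = ("twi", "neighbourhood_height", "pulse_density_diff")
    n_basis: int = 10
    log_smooth: bool = True           # model the smooth on log(size)

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")
        if self.n_basis < 4:
            raise ValueError("need at least 4 basis functions")


class _PSplineBasis:
    """Cubic B-splines on equally spaced knots with a D2 penalty, split into
    penalty null space (fixed) and whitened range space (random)."""

    def __init__(self, x: np.ndarray, n_basis: int):
        self.lo, self.hi = float(x.min()), float(x.max())
        if self.hi <= self.lo:
            raise ValueError("smooth covariate has zero range")
        n_int = n_basis - 3
        dt = (self.hi - self.lo) / n_int
        self.knots = self.lo + dt * np.arange(-3, n_int + 4)
        # clip targets: the exact base interval of the spline space
        self.lo, self.hi = float(self.knots[3]), float(self.knots[-4])
        self.n_basis = n_basis
        d2 = np.diff(np.eye(n_basis), n=2, axis=0)
        S = d2.T @ d2
        vals, vecs = np.linalg.eigh(S)
        self.U0 = vecs[:, :2]               # null space: constant + linear
        self.Up = vecs[:, 2:]
        self.lam = vals[2:]

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, 3).toarray()

    def split(self, B: np.ndarray):
        """(fixed columns, whitened random columns)."""
        return B @ self.U0, (B @ self.Up) / np.sqrt(self.lam)


def _reml_score(loggamma, ytil, Xs, Zs, n, scale_known):
    gamma = np.exp(loggamma)
    M = Zs.T @ Zs
    A = np.eye(M.shape[0]) + gamma * M
    Ainv_ZtX = np.linalg.solve(A, Zs.T @ Xs)
    Ainv_Zty = np.linalg.solve(A, Zs.T @ ytil)
    XtVX = Xs.T @ Xs - gamma * (Xs.T @ Zs) @ Ainv_ZtX
    XtVy = Xs.T @ ytil - gamma * (Xs.T @ Zs) @ Ainv_Zty
    ytVy = ytil @ ytil - gamma * (Zs.T @ ytil) @ Ainv_Zty
    alpha = np.linalg.solve(XtVX, XtVy)
    quad = max(ytVy - XtVy @ alpha, 1e-300)
    sign, logdet_A = np.linalg.slogdet(A)
    sign2, logdet_X = np.linalg.slogdet(XtVX)
    p = Xs.shape[1]
    if scale_known:
        return 0.5 * (logdet_A + logdet_X + quad)
    return 0.5 * (logdet_A + logdet_X + (n - p) * np.log(quad))


def _select_gamma(ytil, Xs, Zs, scale_known=False):
    n = len(ytil)
    res = minimize_scalar(
        _reml_score,
        bounds=(-18.0, 18.0),
        method="bounded",
        args=(ytil, Xs, Zs, n, scale_known),
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def _penalized_fit(ytil, Xs, Zs, gamma):
    """Weighted penalized least squares at fixed variance ratio gamma."""
    C = np.hstack([Xs, Zs])
    p, q = Xs.shape[1], Zs.shape[1]
    pen = np.zeros((p + q, p + q))
    pen[p:, p:] = np.eye(q) / gamma
    CtC = C.T @ C
    H = CtC + pen
    coef = np.linalg.solve(H, C.T @ ytil)
    Hinv = np.linalg.inv(H)
    edf = float(np.trace(Hinv @ CtC))
    return coef, Hinv, edf, CtC


@dataclass
class GamFit:
    spec: GamSpec
    basis: _PSplineBasis = field(repr=False)
    alpha: np.ndarray = field(repr=False)       # fixed: [smooth null (2), linear terms]
    b: np.ndarray = field(repr=False)           # whitened random coefficients
    gamma: float = 1.0                          # variance ratio (smoothing)
    scale: float = 1.0                          # sigma^2 (1 for binomial)
    edf_smooth: float = 0.0
    edf_total: float = 0.0
    deviance: float = 0.0
    coef_table: pd.DataFrame = None
    standardize: dict = field(default_factory=dict)  # col -> (mean, sd) raw scale
    train_smooth: np.ndarray = field(repr=False, default=None)  # raw smooth covariate
    train_linear_raw: pd.DataFrame = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)      # response scale
    deviance_residuals: np.ndarray = field(repr=False, default=None)
    Vb: np.ndarray = field(repr=False, default=None)

    def _design(self, smooth_raw, linear_raw: dict):
        s = np.log(np.asarray(smooth_raw, dtype=float)) if self.spec.log_smooth else np.asarray(smooth_raw, dtype=float)
        extrapolated = (s < self.basis.lo) | (s > self.basis.hi)
        B = self.basis.design(s)
        Xf0, Z = self.basis.split(B)
        lin_cols = []
        for name in self.spec.linear:
            mu, sd = self.standardize[name]
            lin_cols.append((np.asarray(linear_raw[name], dtype=float) - mu) / sd)
        Xf = np.column_stack([Xf0] + lin_cols) if lin_cols else Xf0
        return Xf, Z, extrapolated

    def predict(self, smooth_raw, linear_raw: dict, response_scale: bool = True):
        """Predict at raw-scale covariates; returns (values, extrapolation mask)."""
        Xf, Z, extra = self._design(smooth_raw, linear_raw)
        eta = Xf @ self.alpha + Z @ self.b
        if self.spec.family == "binomial" and response_scale:
            eta = 1.0 / (1.0 + np.exp(-eta))
        return eta, extra


def fit_gam(data: pd.DataFrame, spec: GamSpec, fixed_gamma: float | None = None) -> GamFit:
    """Fit the additive model; complete cases only, deterministic.

    ``fixed_gamma`` bypasses REML selection of the smoothing variance ratio;
    a very small value forces the smooth to its penalty null space (a linear
    trend), which must reproduce ordinary least squares on the same design.

    Raises on rank deficiency, on a binomial response without both classes
    (separation), or on IRLS divergence.
    """
    cols = [spec.response, spec.smooth, *spec.linear]
    d = data[cols].dropna()
    n = len(d)
    if n < 10 * spec.n_basis:
        warnings.warn(f"only {n} complete cases; smooth may be poorly identified")
    y = d[spec.response].to_numpy(dtype=float)

    s_raw = d[spec.smooth].to_numpy(dtype=float)
    s = np.log(s_raw) if spec.log_smooth else s_raw
    basis = _PSplineBasis(s, spec.n_basis)
    B = basis.design(s)
    Xf0, Z = basis.split(B)

    standardize = {}
    lin_cols = []
    for name in spec.linear:
        v = d[name].to_numpy(dtype=float)
        mu, sd = float(v.mean()), float(v.std(ddof=0))
        if sd == 0:
            raise ValueError(f"linear term '{name}' is constant (rank deficient)")
        standardize[name] = (mu, sd)
        lin_cols.append((v - mu) / sd)
    Xf = np.column_stack([Xf0] + lin_cols) if lin_cols else Xf0
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")

    p_null = 2  # smooth null-space columns

    if spec.family == "gaussian":
        gamma = fixed_gamma if fixed_gamma is not None else _select_gamma(y, Xf, Z, scale_known=False)
        coef, Hinv, edf_total, CtC = _penalized_fit(y, Xf, Z, gamma)
        eta = np.hstack([Xf, Z]) @ coef
        rss = float(((y - eta) ** 2).sum())
        scale = rss / (n - edf_total)
        mu = eta
        dev_resid = (y - mu) / np.sqrt(scale)
        deviance = rss
        w = np.ones(n)
    else:
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])) or len(uniq) < 2:
            raise ValueError("binomial response must contain both 0s and 1s")
        eta = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6)) * np.ones(n)
        gamma = 1.0
        coef = None
        for it in range(60):
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1 - mu), 1e-8, None)
            z = eta + (y - mu) / w
            sqw = np.sqrt(w)
            ytil, Xs, Zs = z * sqw, Xf * sqw[:, None], Z * sqw[:, None]
            gamma = fixed_gamma if fixed_gamma is not None else _select_gamma(ytil, Xs, Zs, scale_known=True)
            coef, Hinv, edf_total, CtC = _penalized_fit(ytil, Xs, Zs, gamma)
            eta_new = np.hstack([Xf, Z]) @ coef
            if np.max(np.abs(eta_new - eta)) < 1e-7 * (1 + np.max(np.abs(eta))):
                eta = eta_new
                break
            eta = eta_new
        else:
            raise RuntimeError("binomial IRLS failed to converge")
        if np.max(np.abs(eta)) > 30:
            raise ValueError("complete or quasi-complete separation detected")
        mu = 1.0 / (1.0 + np.exp(-eta))
        scale = 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            d_i = -2 * (y * np.log(np.where(y == 1, mu, 1)) + (1 - y) * np.log(np.where(y == 0, 1 - mu, 1)))
        deviance = float(d_i.sum())
        dev_resid = np.sign(y - mu) * np.sqrt(np.maximum(d_i, 0))

    p_fix = Xf.shape[1]
    alpha = coef[:p_fix]
    b = coef[p_fix:]
    Vb = scale * Hinv
    # effective df of the smooth: total minus linear terms minus intercept part
    edf_smooth = edf_total - (p_fix - p_null)

    names = [f"smooth_null_{i}" for i in range(p_null)] + list(spec.linear)
    ses = np.sqrt(np.diag(Vb)[:p_fix])
    stat = alpha / ses
    coef_table = pd.DataFrame(
        {"term": names, "estimate": alpha, "se": ses, "statistic": stat}
    )

    return GamFit(
        spec=spec,
        basis=basis,
        alpha=alpha,
        b=b,
        gamma=gamma,
        scale=scale,
        edf_smooth=edf_smooth,
        edf_total=edf_total,
        deviance=deviance,
        coef_table=coef_table,
        standardize=standardize,
        train_smooth=s_raw,
        train_linear_raw=d[list(spec.linear)].copy(),
        fitted=mu,
        residuals=y - mu,
        deviance_residuals=dev_resid,
        Vb=Vb,
    )


def linear_coefficient(fit: GamFit, term: str):
    """(estimate, se) of a standardized linear term."""
    row = fit.coef_table[fit.coef_table["term"] == term]
    if row.empty:
        raise KeyError(term)
    return float(row["estimate"].iloc[0]), float(row["se"].iloc[0])


def predict_conditional(
    fit: GamFit,
    covariate: str,
    fixed_raw: dict | None = None,
    size_percentiles: tuple = (5.0, 95.0),
    n_points: int = 100,
) -> pd.DataFrame:
    """Prediction curves over the size range at low (5th pct), mean and high
    (95th pct) values of one covariate, the other covariates held at their
    means and any ``fixed_raw`` overrides (e.g. pulse difference = 0) applied
    on the raw scale."""
    fixed_raw = fixed_raw or {}
    s_grid = np.linspace(
        np.percentile(fit.train_smooth, size_percentiles[0]),
        np.percentile(fit.train_smooth, size_percentiles[1]),
        n_points,
    )
    levels = {
        "low": float(np.percentile(fit.train_linear_raw[covariate], 5)),
        "mean": float(fit.train_linear_raw[covariate].mean()),
        "high": float(np.percentile(fit.train_linear_raw[covariate], 95)),
    }
    frames = []
    for label, value in levels.items():
        raw = {}
        for name in fit.spec.linear:
            if name == covariate:
                raw[name] = np.full(n_points, value)
            elif name in fixed_raw:
                raw[name] = np.full(n_points, float(fixed_raw[name]))
            else:
                raw[name] = np.full(n_points, float(fit.train_linear_raw[name].mean()))
        pred, extra = fit.predict(s_grid, raw)
        frames.append(
            pd.DataFrame(
                {"size": s_grid, "level": label, "covariate_value": value,
                 "prediction": pred, "extrapolated": extra}
            )
        )
    return pd.concat(frames, ignore_index=True)


def residual_spatial_autocorrelation(
    residuals,
    x,
    y,
    n_bins: int = 10,
    max_dist: float | None = None,
    n_permutations: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned Moran's I correlogram of model residuals with a permutation
    envelope (2.5%/97.5% of I under random relabelling).

    Distance classes with fewer than 2 pairs are dropped with a warning.
    """
    r = np.asarray(residuals, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(r)
    ii, jj = np.triu_indices(n, k=1)
    dist = np.hypot(x[ii] - x[jj], y[ii] - y[jj])
    if max_dist is None:
        max_dist = float(dist.max())
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_permutations)]

    rc = r - r.mean()
    denom = float((rc**2).sum())
    rows = []
    for b in range(n_bins):
        if b < n_bins - 1:
            sel = (dist >= edges[b]) & (dist < edges[b + 1])
        else:
            sel = (dist >= edges[b]) & (dist <= edges[b + 1])
        npairs = int(sel.sum())
        if npairs < 2:
            warnings.warn(f"distance class {b} has {npairs} pair(s); dropped")
            continue
        bi, bj = ii[sel], jj[sel]
        s0 = 2.0 * npairs

        def moran(vals):
            vc = vals - vals.mean()
            return (n / s0) * 2.0 * float((vc[bi] * vc[bj]).sum()) / float((vc**2).sum())

        obs = (n / s0) * 2.0 * float((rc[bi] * rc[bj]).sum()) / denom
        sims = np.array([moran(r[p]) for p in perms])
        rows.append(
            dict(
                bin=b,
                dist_lo=edges[b],
                dist_hi=edges[b + 1],
                n_pairs=npairs,
                moran_i=obs,
                env_lo=float(np.quantile(sims, 0.025)),
                env_hi=float(np.quantile(sims, 0.975)),
                inside_envelope=bool(np.quantile(sims, 0.025) <= obs <= np.quantile(sims, 0.975)),
            )
        )
    return pd.DataFrame(rows)
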