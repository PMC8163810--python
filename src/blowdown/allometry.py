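"""Top-of-canopy height to aboveground carbon: fit, predict, propagate.

The core model is the power allometry ``AGBD = a * TCH**b`` (Mg ha^-1)
fitted to plot observations by Gaussian maximum likelihood, with residual
scatter sigma on the AGBD scale.  Predictions are converted to aboveground
carbon density (ACD, Mg C ha^-1) with a constant carbon fraction (0.47).
Uncertainty is propagated with a Monte Carlo parametric bootstrap: each
draw adds independent N(0, sigma) residual noise per cell (and, optionally,
perturbs (a, b) from the asymptotic MLE covariance), truncates at zero, and
converts to carbon; 95% intervals are percentile intervals over draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .rasters import HeightRaster

CARBON_FRACTION = 0.47

__all__ = [
    "AllometricFit",
    "AcdMap",
    "AcdChange",
    "fit_allometry",
    "predict_agbd",
    "agbd_to_acd",
    "monte_carlo_acd",
    "monte_carlo_acd_pair",
    "acd_change",
]


@dataclass
class AllometricFit:
    """Maximum-likelihood fit of AGBD = a * TCH**b with Gaussian residuals."""

    a: float
    b: float
    sigma: float       # residual SD, Mg ha^-1 (MLE, divisor n)
    r2: float
    rmse_pct: float    # RMSE as % of mean observed AGBD
    n: int
    cov_ab: np.ndarray = field(repr=False, default=None)  # asymptotic cov of (a, b)

    def predict(self, tch):
        return self.a * np.asarray(tch, dtype=float) ** self.b


def fit_allometry(plots: pd.DataFrame) -> AllometricFit:
    """Fit the power allometry to a plot table (columns tch_m, agbd_mg_ha).

    Maximizing the Gaussian likelihood in (a, b, sigma) is equivalent to
    least squares in (a, b) with sigma set to the RMS residual; the solve
    uses an analytic Jacobian started from the log-log OLS line.
    """
    tch = np.asarray(plots["tch_m"], dtype=float)
    agbd = np.asarray(plots["agbd_mg_ha"], dtype=float)
    if len(tch) < 3:
        raise ValueError("need at least 3 plots")
    if np.unique(tch).size < 2:
        raise ValueError("degenerate plot table: all TCH values identical")
    if np.any(tch <= 0):
        raise ValueError("TCH must be positive")
    sst = float(np.sum((agbd - agbd.mean()) ** 2))
    if sst == 0:
        raise ValueError("degenerate plot table: AGBD has zero variance")

    # init from log-log OLS on strictly positive observations
    pos = agbd > 0
    slope, intercept = np.polyfit(np.log(tch[pos]), np.log(agbd[pos]), 1)
    x0 = np.array([np.exp(intercept), slope])

    def resid(p):
        return p[0] * tch ** p[1] - agbd

    def jac(p):
        t_b = tch ** p[1]
        return np.column_stack([t_b, p[0] * t_b * np.log(tch)])

    sol = least_squares(resid, x0, jac=jac, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=10_000)
    if not sol.success:
        raise RuntimeError(f"allometry fit did not converge: {sol.message}")
    a, b = sol.x
    if a <= 0:
        raise RuntimeError("allometry fit produced non-positive coefficient")
    sse = float(np.sum(sol.fun**2))
    n = len(tch)
    sigma = float(np.sqrt(sse / n))
    jtj = sol.jac.T @ sol.jac
    cov = sigma**2 * np.linalg.pinv(jtj)
    rmse_pct = float(sigma / agbd.mean() * 100.0)
    return AllometricFit(float(a), float(b), sigma, 1.0 - sse / sst, rmse_pct, n, cov)


def predict_agbd(fit: AllometricFit, tch_raster: HeightRaster) -> HeightRaster:
    """Apply the fitted allometry per cell; nodata propagates, TCH=0 -> 0."""
    with np.errstate(invalid="ignore"):
        values = fit.predict(tch_raster.values)
    return HeightRaster(values, tch_raster.resolution_m, tch_raster.origin,
                        tch_raster.crs)


def agbd_to_acd(agbd, carbon_fraction: float = CARBON_FRACTION):
    """Biomass to carbon: element-wise multiplication by the carbon fraction."""
    if isinstance(agbd, HeightRaster):
        return HeightRaster(agbd.values * carbon_fraction, agbd.resolution_m,
                            agbd.origin, agbd.crs)
    return np.asarray(agbd, dtype=float) * carbon_fraction


@dataclass
class AcdMap:
    """ACD map (Mg C ha^-1) with per-cell and landscape Monte Carlo intervals.

    ``values`` is the noise-free prediction converted to carbon; ``draws``
    holds the full draw stack (n_draws, rows, cols) so change maps can
    difference paired draws.
    """

    values: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    resolution_m: float
    origin: tuple[float, float]
    carbon_fraction: float
    landscape_mean: float
    landscape_ci: tuple[float, float]
    draws: np.ndarray = field(repr=False, default=None)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def _acd_draws(fit, tch_values, n_draws, rng, include_parameter_uncertainty,
               carbon_fraction, param_draws=None):
    mask = np.isfinite(tch_values)
    if param_draws is None:
        if include_parameter_uncertainty:
            # sample (log a, b): keeps the coefficient positive; covariance
            # mapped by the delta method from the (a, b) asymptotic covariance
            jac = np.array([[1.0 / fit.a, 0.0], [0.0, 1.0]])
            cov_log = jac @ fit.cov_ab @ jac.T
            draws_log = rng.multivariate_normal([np.log(fit.a), fit.b], cov_log,
                                                size=n_draws)
            param_draws = np.column_stack([np.exp(draws_log[:, 0]),
                                           draws_log[:, 1]])
        else:
            param_draws = np.tile([fit.a, fit.b], (n_draws, 1))
    tch_flat = tch_values[mask]
    preds = param_draws[:, 0:1] * tch_flat[np.newaxis, :] ** param_draws[:, 1:2]
    noise = rng.normal(0.0, fit.sigma, preds.shape)
    agbd = np.clip(preds + noise, 0.0, None)
    draws = np.full((n_draws,) + tch_values.shape, np.nan)
    draws[:, mask] = agbd * carbon_fraction
    return draws, param_draws


def _summarize_draws(fit, tch_raster, draws, carbon_fraction):
    central = np.clip(predict_agbd(fit, tch_raster).values, 0.0, None) * carbon_fraction
    ci_low = np.nanpercentile(draws, 2.5, axis=0)
    ci_high = np.nanpercentile(draws, 97.5, axis=0)
    land = np.nanmean(draws, axis=(1, 2))
    return AcdMap(
        values=central,
        ci_low=ci_low,
        ci_high=ci_high,
        resolution_m=tch_raster.resolution_m,
        origin=tch_raster.origin,
        carbon_fraction=carbon_fraction,
        landscape_mean=float(np.nanmean(central)),
        landscape_ci=(float(np.percentile(land, 2.5)), float(np.percentile(land, 97.5))),
        draws=draws,
    )


def monte_carlo_acd(fit: AllometricFit, tch_raster: HeightRaster, n_draws: int = 1000,
                    seed: int = 0, include_parameter_uncertainty: bool = False,
                    carbon_fraction: float = CARBON_FRACTION) -> AcdMap:
    """Monte Carlo ACD map with 95% percentile intervals.

    Default draws perturb only the residual term (parametric bootstrap of
    the fitted Gaussian scatter).  ``include_parameter_uncertainty=True``
    additionally draws (a, b) from the asymptotic MLE covariance — required
    if the landscape-mean interval is to cover the true generating curve,
    since residual noise alone averages out over many cells while fit error
    does not.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    draws, _ = _acd_draws(fit, tch_raster.values, n_draws, rng,
                          include_parameter_uncertainty, carbon_fraction)
    return _summarize_draws(fit, tch_raster, draws, carbon_fraction)


def monte_carlo_acd_pair(fit: AllometricFit, tch_pre: HeightRaster,
                         tch_post: HeightRaster, n_draws: int = 1000, seed: int = 0,
                         include_parameter_uncertainty: bool = False,
                         carbon_fraction: float = CARBON_FRACTION
                         ) -> tuple[AcdMap, AcdMap]:
    """Paired Monte Carlo maps for two epochs under one shared fit.

    Parameter draws are shared between epochs (the same allometry applies
    before and after the disturbance) while residual draws are independent,
    so differencing paired draws propagates uncertainty into change maps
    correctly.
    """
    if not tch_pre.same_grid(tch_post):
        raise ValueError("pre and post TCH rasters must share one grid")
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    draws_pre, params = _acd_draws(fit, tch_pre.values, n_draws, rng,
                                   include_parameter_uncertainty, carbon_fraction)
    draws_post, _ = _acd_draws(fit, tch_post.values, n_draws, rng,
                               include_parameter_uncertainty, carbon_fraction,
                               param_draws=params)
    return (_summarize_draws(fit, tch_pre, draws_pre, carbon_fraction),
            _summarize_draws(fit, tch_post, draws_post, carbon_fraction))


@dataclass
class AcdChange:
    """Cell-wise and landscape ACD change (post minus pre) with intervals."""

    delta: np.ndarray              # Mg C ha^-1 per cell
    pct_change: np.ndarray         # % of pre, per cell
    landscape_delta: float
    landscape_delta_ci: tuple[float, float]
    landscape_pct: float           # % change of the landscape mean
    landscape_pct_ci: tuple[float, float]


def acd_change(pre: AcdMap, post: AcdMap) -> AcdChange:
    """Difference two ACD maps; intervals come from differencing paired draws.

    The two maps must carry draw stacks of equal shape built with shared
    parameter draws (see :func:`monte_carlo_acd_pair`).
    """
    if pre.values.shape != post.values.shape or not np.allclose(pre.origin, post.origin):
        raise ValueError("ACD maps are not aligned")
    delta = post.values - pre.values
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(pre.values > 0, delta / pre.values * 100.0, np.nan)
    if pre.draws is None or post.draws is None or pre.draws.shape != post.draws.shape:
        raise ValueError("paired draw stacks required; build maps with monte_carlo_acd_pair")
    d_land = np.nanmean(post.draws, axis=(1, 2)) - np.nanmean(pre.draws, axis=(1, 2))
    pre_land = np.nanmean(pre.draws, axis=(1, 2))
    pct_land = d_land / pre_land * 100.0
    return AcdChange(
        delta=delta,
        pct_change=pct,
        landscape_delta=float(np.nanmean(post.values) - np.nanmean(pre.values)),
        landscape_delta_ci=(float(np.percentile(d_land, 2.5)),
                            float(np.percentile(d_land, 97.5))),
        landscape_pct=float((np.nanmean(post.values) - np.nanmean(pre.values))
                            / np.nanmean(pre.values) * 100.0),
        landscape_pct_ci=(float(np.percentile(pct_land, 2.5)),
                          float(np.percentile(pct_land, 97.5))),
    )
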