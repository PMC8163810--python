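"""Synthetic forest landscapes, field plots and mixed reflectance pixels.

Every downstream stage of the analysis — canopy rasterization, carbon
allometry, gap power-law inference, height-class transition projection and
spectral unmixing — can be exercised on data from this module, which builds
landscapes with the statistical structure the analysis assumes:

* a spatially autocorrelated canopy height surface with disk-shaped gaps
  whose pixel areas follow a discrete power law (Zeta distribution),
* field plots obeying a power-law height-to-biomass allometry with additive
  Gaussian residuals, and
* reflectance pixels that are exact linear mixtures of endmember spectra
  plus optional noise.

All generators take one explicit seed; identical seeds give bit-identical
output.  True quantities (per-pixel height change, removed canopy-volume
fraction, generating parameters) are recorded so tests can compare
estimates against truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.special import zeta as riemann_zeta

from .rasters import HeightRaster, MultibandRaster
from .points import PointSet

__all__ = [
    "SyntheticForestConfig",
    "AllometrySimConfig",
    "sample_zeta",
    "generate_chm",
    "apply_blowdown",
    "BlowdownResult",
    "generate_plots",
    "generate_mixed_pixels",
    "sample_points_from_surface",
    "synthetic_endmembers",
    "generate_dtm",
]


@dataclass
class SyntheticForestConfig:
    """Parameters of the synthetic canopy-height landscape.

    Defaults emulate an old-growth tropical wet-forest canopy: mean height
    22.2 m with ~6 m spatial variation, 1.25 m pixels, and gap areas (in
    pixels) following a Zeta distribution with exponent 2.
    """

    extent_m: float = 320.0
    chm_resolution_m: float = 1.25
    mean_canopy_height_m: float = 22.2
    height_sd_m: float = 6.0
    gap_lambda: float = 2.0
    n_gaps: int = 150
    gap_floor_height_m: float = 0.5
    smooth_window_px: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_m <= 0:
            raise ValueError("extent_m must be positive")
        if self.chm_resolution_m <= 0:
            raise ValueError("chm_resolution_m must be positive")
        if self.gap_lambda <= 1:
            raise ValueError("gap_lambda must exceed 1")
        if self.n_gaps < 0:
            raise ValueError("n_gaps must be >= 0")
        if self.gap_floor_height_m < 0:
            raise ValueError("gap_floor_height_m must be >= 0")
        if self.smooth_window_px < 1:
            raise ValueError("smooth_window_px must be >= 1")


@dataclass
class AllometrySimConfig:
    """Parameters of the simulated height-to-biomass plot network.

    Defaults give plot-mean AGBD near 173 Mg ha^-1 with residual scatter of
    16 Mg ha^-1 (9.2% of the mean), the fit quality of well-constrained
    tropical lidar allometries.
    """

    a_true: float = 1.28
    b_true: float = 1.6
    residual_sd: float = 16.0
    n_plots: int = 18
    tch_range_m: tuple[float, float] = (14.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a_true <= 0:
            raise ValueError("a_true must be positive")
        if self.n_plots < 3:
            raise ValueError("n_plots must be >= 3")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        lo, hi = self.tch_range_m
        if not (0 < lo < hi):
            raise ValueError("tch_range_m must satisfy 0 < min < max")


# ---------------------------------------------------------------------------
# Zeta (discrete power law) sampling
# ---------------------------------------------------------------------------

def sample_zeta(lam: float, size: int, rng: np.random.Generator,
                k_max: int = 10**6) -> np.ndarray:
    """Draw integer sizes k >= 1 with P(k) proportional to k^-lam.

    Inverse-CDF sampling on a cumulative table truncated at ``k_max``; the
    tail mass beyond ``k_max`` is assigned to ``k_max``.  Exact to the
    truncation for any lam > 1 (tail mass < 1e-6 of total for lam >= 2).
    """
    if lam <= 1:
        raise ValueError("lam must exceed 1 for a normalizable Zeta law")
    ks = np.arange(1, k_max + 1, dtype=float)
    pmf = ks ** (-lam) / riemann_zeta(lam)
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0  # tail mass -> k_max
    u = rng.random(size)
    return np.searchsorted(cdf, u, side="left") + 1


# ---------------------------------------------------------------------------
# Canopy height landscape
# ---------------------------------------------------------------------------

def _carve_disks(values: np.ndarray, sizes_px: np.ndarray, floor: np.ndarray | float,
                 rng: np.random.Generator) -> np.ndarray:
    """Set disk-shaped patches of the given pixel areas to ``floor``.

    Returns the boolean mask of carved pixels.  Overlapping disks merge; the
    later carving wins (identical floor makes this moot for a scalar floor).
    """
    ny, nx = values.shape
    carved = np.zeros(values.shape, dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for k in sizes_px:
        r = max(np.sqrt(k / np.pi), 0.51)  # radius in pixels; >= 1 px carved
        cy = rng.uniform(0, ny)
        cx = rng.uniform(0, nx)
        disk = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= r**2
        if not disk.any():
            disk[min(int(cy), ny - 1), min(int(cx), nx - 1)] = True
        values[disk] = floor
        carved |= disk
    return carved


def generate_chm(config: SyntheticForestConfig) -> HeightRaster:
    """Generate a canopy height model with power-law-sized gaps.

    Background heights are truncated-at-zero Gaussian, smoothed with a
    moving-average window to create spatial autocorrelation (and rescaled so
    the configured standard deviation survives the smoothing); ``n_gaps``
    disk patches with Zeta-distributed pixel areas are then set to the gap
    floor height.  The raster has no nodata pixels.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.extent_m / config.chm_resolution_m))
    noise = rng.normal(0.0, 1.0, (n, n))
    if config.smooth_window_px > 1:
        noise = uniform_filter(noise, size=config.smooth_window_px, mode="wrap")
        sd = noise.std()
        if sd > 0:
            noise /= sd
    values = config.mean_canopy_height_m + config.height_sd_m * noise
    values = np.clip(values, 0.0, None)

    if config.n_gaps > 0:
        sizes = sample_zeta(config.gap_lambda, config.n_gaps, rng)
        if sizes.max() > n * n:
            raise ValueError(
                f"sampled gap of {sizes.max()} px exceeds the {n}x{n} raster; "
                "increase extent_m or gap_lambda"
            )
        _carve_disks(values, sizes, config.gap_floor_height_m, rng)

    return HeightRaster(values, config.chm_resolution_m, (0.0, 0.0))


@dataclass
class BlowdownResult:
    """Post-disturbance raster plus the truth needed by test oracles."""

    chm: HeightRaster
    true_change: np.ndarray  # post - pre heights (m), per pixel
    removed_fraction: float  # realized fraction of summed canopy height removed
    disturbed_mask: np.ndarray = field(repr=False, default=None)


def apply_blowdown(chm: HeightRaster, severity: float, gap_lambda_post: float = 1.7,
                   seed: int = 0, floor_height_m: float = 1.0,
                   tolerance: float = 0.02, batch: int = 20) -> BlowdownResult:
    """Carve additional power-law-sized patches until about ``severity`` of
    the total canopy volume (summed pixel height) is removed.

    Patches are lowered to near-ground height (``floor_height_m``).  Patch
    areas follow Zeta(``gap_lambda_post``); a smaller exponent than the
    intact landscape's gives the increased prevalence of large openings
    characteristic of convective-downdraft damage.  Because the size law is
    heavy-tailed, a sampled patch whose removal would overshoot the target
    is shrunk to the remaining volume deficit, so the realized removed
    fraction lands within ``tolerance`` of ``severity`` by construction.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pre = chm.values
    post = pre.copy()
    total = float(np.nansum(pre))
    disturbed = np.zeros(pre.shape, dtype=bool)
    if severity > 0 and total > 0:
        floor = min(floor_height_m, float(np.nanmin(pre)))
        guard = 0
        while True:
            removed = (total - float(np.nansum(post))) / total
            if removed >= severity - tolerance:
                break
            sizes = sample_zeta(gap_lambda_post, batch, rng)
            for k in sizes:
                removed = (total - float(np.nansum(post))) / total
                if removed >= severity - tolerance:
                    break
                # cap patch area at the remaining deficit to avoid overshoot
                deficit = (severity - removed) * total
                excess = post[~disturbed] - floor
                mean_excess = float(np.nanmean(np.clip(excess, 1e-6, None)))
                k_eff = int(min(k, max(1, np.floor(deficit / mean_excess))))
                disturbed |= _carve_disks(post, np.array([k_eff]), floor, rng)
            guard += 1
            if guard > 10_000:  # pragma: no cover - defensive
                raise RuntimeError("blowdown carving failed to reach severity")
    removed = (total - float(np.nansum(post))) / total if total > 0 else 0.0
    out = HeightRaster(post, chm.resolution_m, chm.origin, chm.crs)
    return BlowdownResult(out, post - pre, removed, disturbed)


# ---------------------------------------------------------------------------
# Field plots
# ---------------------------------------------------------------------------

def generate_plots(config: AllometrySimConfig):
    """Simulate the plot network used to calibrate the height-biomass model.

    Returns a DataFrame with columns ``plot_id, tch_m, agbd_mg_ha`` where
    AGBD = a_true * TCH^b_true + N(0, residual_sd), truncated at zero, and
    TCH is uniform over ``tch_range_m``.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    lo, hi = config.tch_range_m
    tch = rng.uniform(lo, hi, config.n_plots)
    agbd = config.a_true * tch**config.b_true
    if config.residual_sd > 0:
        agbd = agbd + rng.normal(0.0, config.residual_sd, config.n_plots)
    agbd = np.clip(agbd, 0.0, None)
    return pd.DataFrame(
        {
            "plot_id": [f"P{i + 1:02d}" for i in range(config.n_plots)],
            "tch_m": tch,
            "agbd_mg_ha": agbd,
        }
    )


# ---------------------------------------------------------------------------
# Mixed reflectance pixels
# ---------------------------------------------------------------------------

def synthetic_endmembers():
    """A synthetic 6-band endmember set (PV, NPV, shade).

    Shapes mimic the broadband behaviour of green vegetation (red edge and
    NIR plateau), dry woody material (monotone rise through SWIR) and shade
    (uniformly dark).  These are synthetic spectra for testing, not measured
    Landsat endmembers.
    """
    from .unmixing import EndmemberSet

    bands = ["blue", "green", "red", "nir", "swir1", "swir2"]
    spectra = np.array(
        [
            [0.02, 0.05, 0.03, 0.45, 0.22, 0.10],  # photosynthetic vegetation
            [0.08, 0.12, 0.18, 0.30, 0.42, 0.35],  # non-photosynthetic vegetation
            [0.01, 0.01, 0.01, 0.02, 0.01, 0.01],  # shade
        ]
    )
    return EndmemberSet(spectra=spectra, names=["pv", "npv", "shade"], bands=bands)


def generate_mixed_pixels(fractions: np.ndarray, endmembers, noise_sd: float = 0.0,
                          seed: int = 0, resolution_m: float = 30.0,
                          origin: tuple[float, float] = (0.0, 0.0)) -> MultibandRaster:
    """Build a reflectance raster from per-pixel endmember fractions.

    ``fractions`` has shape (rows, cols, n_endmembers); every pixel's
    fractions must be >= 0 and sum to 1 within 1e-9.  Reflectance is the
    linear mixture of endmember spectra plus optional i.i.d. Gaussian noise.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 3 or fractions.shape[2] != endmembers.spectra.shape[0]:
        raise ValueError("fractions must have shape (rows, cols, n_endmembers)")
    sums = fractions.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("per-pixel fractions must sum to 1 within 1e-9")
    if (fractions < 0).any():
        raise ValueError("fractions must be non-negative")
    refl = np.einsum("ijm,mb->bij", fractions, endmembers.spectra)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        refl = refl + rng.normal(0.0, noise_sd, refl.shape)
    return MultibandRaster(refl, resolution_m, origin, None, list(endmembers.bands))


# ---------------------------------------------------------------------------
# Point and terrain fixtures
# ---------------------------------------------------------------------------

def generate_dtm(extent_m: float, resolution_m: float = 5.0, base_elevation_m: float = 40.0,
                 relief_m: float = 15.0, seed: int = 0) -> HeightRaster:
    """Gently undulating ground-elevation raster (synthetic terrain)."""
    rng = np.random.default_rng(seed)
    n = int(round(extent_m / resolution_m))
    noise = uniform_filter(rng.normal(0, 1, (n, n)), size=max(n // 4, 3), mode="wrap")
    rng_span = noise.max() - noise.min()
    if rng_span > 0:
        noise = (noise - noise.min()) / rng_span
    return HeightRaster(base_elevation_m + relief_m * noise, resolution_m, (0.0, 0.0))


def sample_points_from_surface(chm: HeightRaster, density_pts_m2: float,
                               dtm: HeightRaster | None = None, seed: int = 0,
                               second_return_fraction: float = 0.1,
                               max_scan_angle_deg: float = 20.0,
                               vertical_noise_m: float = 0.1) -> PointSet:
    """Uniform planar scatter of returns over a synthetic canopy surface.

    Elevation is canopy height at the point (nearest CHM pixel) plus ground
    elevation from the DTM (bilinear, if given) plus small vertical noise.
    A fraction of returns are flagged as second returns (placed lower in
    the canopy) and scan angles are uniform within +-``max_scan_angle_deg``,
    so the first-return and scan-angle filters have something to remove.
    This is a geometric scatter, not a beam-physics simulation.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = chm.extent
    area = (xmax - xmin) * (ymax - ymin)
    n = int(round(density_pts_m2 * area))
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)
    j = np.clip(((x - xmin) / chm.resolution_m).astype(int), 0, chm.shape[1] - 1)
    i = np.clip(((y - ymin) / chm.resolution_m).astype(int), 0, chm.shape[0] - 1)
    height = chm.values[i, j]
    ret = np.ones(n, dtype=int)
    n2 = int(round(second_return_fraction * n))
    if n2:
        idx = rng.choice(n, n2, replace=False)
        ret[idx] = 2
        height = height.copy()
        height[idx] *= rng.uniform(0.2, 0.8, n2)
    z = height + rng.normal(0.0, vertical_noise_m, n)
    z = np.clip(z, 0.0, None)
    if dtm is not None:
        from .canopy import _interpolate_dtm

        z = z + _interpolate_dtm(dtm, x, y)
    angle = rng.uniform(-max_scan_angle_deg, max_scan_angle_deg, n)
    return PointSet(x, y, z, ret, angle)
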