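"""Point-cloud filtering and canopy height rasterization.

Implements the processing rules used to make discrete-return lidar epochs
comparable: first-return selection, scan-angle limits, density
homogenization, terrain normalization against a DTM, a constant vertical
bias correction per epoch, and two gridding schemes — a Delaunay TIN
interpolated to 1.25 m pixels (every in-hull pixel gets a height) and a
mean-of-returns grid at 5 m for top-of-canopy height (TCH).

Pixel footprints are half-open ``[x0, x0+res) x [y0, y0+res)`` throughout.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from scipy.spatial import QhullError

from .points import PointSet
from .rasters import HeightChangeRaster, HeightRaster

logger = logging.getLogger(__name__)

__all__ = [
    "filter_returns",
    "subsample_density",
    "height_above_ground",
    "apply_vertical_bias",
    "rasterize_tin",
    "rasterize_mean",
    "height_change",
    "mean_tch",
]


def filter_returns(points: PointSet, max_abs_scan_angle_deg: float = 15.0) -> PointSet:
    """Keep first returns with |scan angle| within the threshold, in order."""
    if len(points) == 0:
        raise ValueError("empty point set")
    keep = (points.return_number == 1) & (
        np.abs(points.scan_angle_deg) <= max_abs_scan_angle_deg
    )
    if not keep.any():
        logger.warning("filter_returns removed every point")
    return points.select(keep)


def subsample_density(points: PointSet, target_density_pts_m2: float, area_m2: float,
                      seed: int = 0) -> PointSet:
    """Uniform random subsample to ``round(target * area)`` points.

    If the set is already at or below the target density the input is
    returned unchanged (with a warning), matching the convention that the
    density filter only ever thins.
    """
    n_target = int(round(target_density_pts_m2 * area_m2))
    if n_target >= len(points):
        logger.warning(
            "subsample_density: %d points already at/below target %d; returning input",
            len(points), n_target,
        )
        return points
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(points), size=n_target, replace=False))
    return points.select(idx)


def _interpolate_dtm(dtm: HeightRaster, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear ground elevation at (x, y); coordinates must be inside the
    DTM extent.  Points in the half-pixel margin outside the center grid are
    clamped to the edge (edge padding)."""
    xmin, ymin, xmax, ymax = dtm.extent
    outside = (x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)
    n_out = int(outside.sum())
    if n_out:
        raise ValueError(f"{n_out} points fall outside the DTM extent")
    xs, ys = dtm.pixel_centers()
    interp = RegularGridInterpolator((ys, xs), dtm.values, method="linear",
                                     bounds_error=False, fill_value=None)
    yc = np.clip(y, ys[0], ys[-1])
    xc = np.clip(x, xs[0], xs[-1])
    # fill_value=None extrapolates linearly; clamping first makes it edge padding
    return interp(np.column_stack([yc, xc]))


def height_above_ground(points: PointSet, dtm: HeightRaster) -> PointSet:
    """Replace elevation with height above the DTM surface, clamped at 0."""
    ground = _interpolate_dtm(dtm, points.x_m, points.y_m)
    return points.with_z(np.clip(points.z_m - ground, 0.0, None))


def apply_vertical_bias(points: PointSet, bias_m: float) -> PointSet:
    """Remove a constant vertical bias: z -> z - bias_m."""
    return points.with_z(points.z_m - bias_m)


def _grid_centers(extent, resolution_m):
    xmin, ymin, xmax, ymax = extent
    nx = int(round((xmax - xmin) / resolution_m))
    ny = int(round((ymax - ymin) / resolution_m))
    if nx < 1 or ny < 1:
        raise ValueError("extent smaller than one pixel")
    xs = xmin + (np.arange(nx) + 0.5) * resolution_m
    ys = ymin + (np.arange(ny) + 0.5) * resolution_m
    return xs, ys, nx, ny


def rasterize_tin(points: PointSet, resolution_m: float = 1.25,
                  extent: tuple[float, float, float, float] | None = None) -> HeightRaster:
    """Grid a Delaunay triangulation of the points to pixel centers.

    Every pixel whose center lies inside the convex hull gets the linear
    TIN surface value, so the canopy height model has no interior holes;
    out-of-hull pixels are nodata.
    """
    if len(points) < 3:
        raise ValueError("TIN rasterization needs at least 3 points")
    if extent is None:
        extent = (points.x_m.min(), points.y_m.min(),
                  points.x_m.max(), points.y_m.max())
    xs, ys, nx, ny = _grid_centers(extent, resolution_m)
    try:
        interp = LinearNDInterpolator(
            np.column_stack([points.x_m, points.y_m]), points.z_m
        )
    except QhullError as exc:
        raise ValueError("points are collinear or degenerate; cannot build TIN") from exc
    gx, gy = np.meshgrid(xs, ys)
    values = interp(gx, gy)
    return HeightRaster(values, resolution_m, (extent[0], extent[1]))


def rasterize_mean(points: PointSet, resolution_m: float = 5.0,
                   extent: tuple[float, float, float, float] | None = None) -> HeightRaster:
    """Mean point height per half-open pixel footprint; empty pixels nodata."""
    if extent is None:
        if len(points) == 0:
            raise ValueError("empty point set and no extent given")
        extent = (points.x_m.min(), points.y_m.min(),
                  points.x_m.max(), points.y_m.max())
    xmin, ymin, xmax, ymax = extent
    _, _, nx, ny = _grid_centers(extent, resolution_m)
    j = np.floor((points.x_m - xmin) / resolution_m).astype(int)
    i = np.floor((points.y_m - ymin) / resolution_m).astype(int)
    inside = (i >= 0) & (i < ny) & (j >= 0) & (j < nx)
    i, j, z = i[inside], j[inside], points.z_m[inside]
    total = np.zeros((ny, nx))
    count = np.zeros((ny, nx))
    np.add.at(total, (i, j), z)
    np.add.at(count, (i, j), 1.0)
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.where(count > 0, count, 1.0), np.nan)
    return HeightRaster(values, resolution_m, (xmin, ymin))


def height_change(pre: HeightRaster, post: HeightRaster) -> HeightChangeRaster:
    """Final minus initial height per pixel; nodata where either is nodata."""
    if not pre.same_grid(post):
        raise ValueError("height_change requires identical grid geometry")
    values = post.values - pre.values  # NaN propagates
    return HeightChangeRaster(values, pre.resolution_m, pre.origin, pre.crs)


def mean_tch(tch_raster: HeightRaster, footprint) -> float:
    """Mean of valid pixels whose centers fall inside a footprint.

    ``footprint`` is either a rectangle ``(xmin, ymin, xmax, ymax)`` or a
    boolean mask on the raster grid.
    """
    if isinstance(footprint, np.ndarray) and footprint.dtype == bool:
        sel = footprint & tch_raster.mask
    else:
        xmin, ymin, xmax, ymax = footprint
        xs, ys = tch_raster.pixel_centers()
        in_x = (xs >= xmin) & (xs <= xmax)
        in_y = (ys >= ymin) & (ys <= ymax)
        sel = np.outer(in_y, in_x) & tch_raster.mask
    if not sel.any():
        raise ValueError("footprint overlaps no valid raster pixels")
    return float(tch_raster.values[sel].mean())
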