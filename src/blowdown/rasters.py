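"""Gridded raster containers and GeoTIFF-style I/O.

Rasters are stored row-major with row 0 at the *southern* edge: pixel
``values[i, j]`` covers the half-open footprint
``[x0 + j*res, x0 + (j+1)*res) x [y0 + i*res, y0 + (i+1)*res)`` where
``(x0, y0)`` is the lower-left ``origin``.  Nodata is ``NaN`` in memory and
-9999 on disk.  Files are written north-up (rows flipped) with GeoTIFF
pixel-scale / tiepoint / GDAL-nodata tags so standard GIS software reads
them with correct georeferencing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

NODATA = -9999.0

#: GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class HeightRaster:
    """Canopy height (or ground elevation) above a planar grid, in metres."""

    values: np.ndarray
    resolution_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.resolution_m <= 0:
            raise ValueError("resolution_m must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full pixel footprint."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.resolution_m, y0 + ny * self.resolution_m)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x and y pixel-center coordinates."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        r = self.resolution_m
        xs = x0 + (np.arange(nx) + 0.5) * r
        ys = y0 + (np.arange(ny) + 0.5) * r
        return xs, ys

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) pixels."""
        return np.isfinite(self.values)

    def same_grid(self, other: "HeightRaster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.resolution_m, other.resolution_m)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "HeightRaster":
        return replace(self, values=self.values.copy())


@dataclass
class HeightChangeRaster:
    """Per-pixel final-minus-initial canopy height (m) on a shared grid."""

    values: np.ndarray
    resolution_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str | None = None

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class MultibandRaster:
    """Stack of co-registered bands, shape (bands, rows, cols)."""

    values: np.ndarray
    resolution_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str | None = None
    band_names: list[str] = field(default_factory=list)

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]


def _geo_tags(raster) -> list[tuple]:
    ny = raster.values.shape[-2]
    x0, y0 = raster.origin
    res = float(raster.resolution_m)
    y_top = y0 + ny * res
    desc = {"crs": raster.crs}
    if isinstance(raster, MultibandRaster):
        desc["band_names"] = raster.band_names
    return json.dumps(desc), [
        (_TAG_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y_top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(NODATA)),
    ]


def write_geotiff(raster, path) -> None:
    """Write a :class:`HeightRaster` or :class:`MultibandRaster` to GeoTIFF.

    Single band float32, nodata -9999, north-up row order.
    """
    vals = np.asarray(raster.values, dtype=np.float32)
    vals = np.where(np.isfinite(vals), vals, np.float32(NODATA))
    if vals.ndim == 2:
        vals = vals[np.newaxis]
    # flip rows: in-memory row 0 is the southern edge, file row 0 the northern
    vals = vals[:, ::-1, :]
    data = vals[0] if vals.shape[0] == 1 else vals
    description, tags = _geo_tags(raster)
    tifffile.imwrite(str(path), data, description=description, extratags=tags,
                     photometric="minisblack")


def _read_tags(page):
    res = 1.0
    origin_top = (0.0, 0.0)
    crs = None
    band_names: list[str] = []
    if _TAG_PIXEL_SCALE in page.tags:
        res = float(page.tags[_TAG_PIXEL_SCALE].value[0])
    if _TAG_TIEPOINT in page.tags:
        tp = page.tags[_TAG_TIEPOINT].value
        origin_top = (float(tp[3]), float(tp[4]))
    if 270 in page.tags:
        try:
            desc = json.loads(page.tags[270].value)
            crs = desc.get("crs")
            band_names = desc.get("band_names", [])
        except (json.JSONDecodeError, TypeError):
            pass
    return res, origin_top, crs, band_names


def read_geotiff(path) -> HeightRaster:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(str(path)) as tif:
        vals = tif.asarray().astype(float)
        res, (x0, y_top), crs, _ = _read_tags(tif.pages[0])
    if vals.ndim != 2:
        raise ValueError(f"{path} is not single-band; use read_geotiff_multiband")
    vals = np.where(vals == NODATA, np.nan, vals)[::-1, :]
    origin = (x0, y_top - vals.shape[0] * res)
    return HeightRaster(vals, res, origin, crs)


def read_geotiff_multiband(path) -> MultibandRaster:
    with tifffile.TiffFile(str(path)) as tif:
        vals = tif.asarray().astype(float)
        res, (x0, y_top), crs, band_names = _read_tags(tif.pages[0])
    if vals.ndim == 2:
        vals = vals[np.newaxis]
    vals = np.where(vals == NODATA, np.nan, vals)[:, ::-1, :]
    origin = (x0, y_top - vals.shape[1] * res)
    return MultibandRaster(vals, res, origin, crs, band_names)


def block_average(raster: HeightRaster, factor: int) -> HeightRaster:
    """Aggregate to a coarser grid by averaging ``factor``x``factor`` blocks.

    Trailing rows/columns that do not fill a whole block are dropped.  Blocks
    with no valid pixels become nodata; partially valid blocks average their
    valid pixels.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    ny, nx = raster.values.shape
    ny2, nx2 = ny // factor, nx // factor
    if ny2 == 0 or nx2 == 0:
        raise ValueError("raster smaller than one block")
    v = raster.values[: ny2 * factor, : nx2 * factor]
    v = v.reshape(ny2, factor, nx2, factor)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(v, axis=(1, 3))
    return HeightRaster(out, raster.resolution_m * factor, raster.origin, raster.crs)


def regrid_mean(src: HeightRaster, dst_resolution_m: float,
                dst_origin: tuple[float, float] | None = None,
                dst_shape: tuple[int, int] | None = None) -> HeightRaster:
    """Area-weighted mean resampling onto a coarser (or offset) grid.

    The value of each destination cell is the overlap-area-weighted mean of
    the source pixels it intersects, ignoring nodata source pixels.  Used to
    pair quantities defined on incommensurate grids (e.g. 70 m carbon cells
    against 30 m reflectance pixels).
    """
    x0, y0 = src.origin
    ny, nx = src.values.shape
    res = src.resolution_m
    if dst_origin is None:
        dst_origin = src.origin
    if dst_shape is None:
        dst_shape = (
            int(np.floor((y0 + ny * res - dst_origin[1]) / dst_resolution_m)),
            int(np.floor((x0 + nx * res - dst_origin[0]) / dst_resolution_m)),
        )
    dny, dnx = dst_shape
    if dny < 1 or dnx < 1:
        raise ValueError("destination grid is empty")

    def overlap_1d(n_src, src0, n_dst, dst0, dres):
        # (n_dst, n_src) matrix of interval overlap lengths
        se = src0 + np.arange(n_src + 1) * res
        de = dst0 + np.arange(n_dst + 1) * dres
        lo = np.maximum(de[:-1, None], se[None, :-1])
        hi = np.minimum(de[1:, None], se[None, 1:])
        return np.clip(hi - lo, 0.0, None)

    oy = overlap_1d(ny, y0, dny, dst_origin[1], dst_resolution_m)
    ox = overlap_1d(nx, x0, dnx, dst_origin[0], dst_resolution_m)
    valid = src.mask
    v = np.where(valid, src.values, 0.0)
    num = oy @ v @ ox.T
    den = oy @ valid.astype(float) @ ox.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return HeightRaster(out, dst_resolution_m, dst_origin, src.crs)
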