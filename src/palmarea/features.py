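"""Derived predictors and the 17-band feature stack.

NDVI and its local texture (5x5 moving SD) are computed on the 10 m optical
composite; SAR temporal statistics come in on the same 10 m grid; slope is
derived from the 30 m DEM with Horn's 3x3 method. All layers are then brought
onto the common 20 m analysis grid: block means for the 10 m layers (exact
2x2 aggregation) and bilinear sampling for the coarser slope layer.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .composite import SAR_STAT_BANDS, Composite
from .grid import Raster, bilinear_to, block_mean, is_geographic
from .synth import OPTICAL_BANDS

__all__ = ["FEATURE_NAMES", "ndvi", "moving_sd", "slope", "build_feature_stack"]

#: The 17 predictors, in stack order.
FEATURE_NAMES = OPTICAL_BANDS + (
    "NDVI", "NDVI_SD5", "VV_mean", "VV_sd", "VH_mean", "VH_sd", "SLOPE",
)

ANALYSIS_RES = 20.0  # m


def ndvi(composite: Composite) -> np.ndarray:
    """(B8 - B4) / (B8 + B4); NaN where the denominator is 0 or inputs nodata."""
    b8 = composite.sel("B8").astype(np.float64)
    b4 = composite.sel("B4").astype(np.float64)
    denom = b8 + b4
    out = np.full(b8.shape, np.nan)
    np.divide(b8 - b4, denom, out=out, where=denom != 0)
    return out


def moving_sd(data: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-pixel population SD over a square moving window.

    The window shrinks at image edges to the in-bounds pixels, and NaN pixels
    are excluded from the window statistics (no values are invented outside
    the image). A pixel whose whole window is NaN stays NaN.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 3:
        raise ValueError("window must be >= 3")
    x = np.asarray(data, dtype=np.float64)
    valid = np.isfinite(x)
    x0 = np.where(valid, x, 0.0)

    def winsum(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a, size=window, mode="constant", cval=0.0) * window**2

    n = winsum(valid.astype(np.float64))
    n = np.round(n)  # uniform_filter is float; counts are integral
    s1 = winsum(x0)
    s2 = winsum(x0 * x0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        var = s2 / n - mean * mean
    var = np.clip(var, 0.0, None)
    out = np.sqrt(var)
    out[n < 1] = np.nan
    return out


def slope(dem: Raster, cellsize: float | None = None) -> Raster:
    """Slope in degrees from Horn's 3x3 finite-difference gradient.

    Requires a projected (metric) CRS so that elevation and cell size share
    units; edges use replicated padding, so a flat DEM is exactly 0 even at
    the border.
    """
    if is_geographic(dem.crs):
        raise ValueError("slope requires a projected metric CRS, got a geographic one")
    if dem.data.ndim != 2:
        raise ValueError("DEM must be single-band")
    rx, ry = dem.res
    dx = cellsize if cellsize is not None else rx
    dy = cellsize if cellsize is not None else ry

    z = np.pad(dem.data.astype(np.float64), 1, mode="edge")
    # 3x3 neighbourhood: a b c / d e f / g h i
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, hh, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx)
    dzdy = ((g + 2 * hh + i) - (a + 2 * b + c)) / (8.0 * dy)
    deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return Raster(deg, dem.transform, crs=dem.crs, nodata=float("nan"),
                  band_names=("SLOPE",))


def build_feature_stack(composite: Composite,
                        ndvi_r: np.ndarray,
                        texture_r: np.ndarray,
                        sar_stats: Raster,
                        slope_r: Raster,
                        target_res: float = ANALYSIS_RES) -> Raster:
    """Assemble the 17 predictors on the common analysis grid.

    The optical composite, NDVI, texture, and SAR statistics must share the
    same fine grid; they are aggregated by block mean to ``target_res``. The
    slope layer may live on its own (coarser) grid and is sampled bilinearly.
    Pixels that are nodata in any optical band are nodata in every layer.
    """
    if sar_stats.crs != composite.crs or slope_r.crs != composite.crs:
        raise ValueError("all inputs must share the composite's CRS "
                         "(reprojection is not supported)")
    if tuple(sar_stats.transform) != tuple(composite.transform):
        raise ValueError("SAR statistics must be on the composite grid")
    if tuple(sar_stats.band_names or ()) != SAR_STAT_BANDS:
        raise ValueError(f"SAR stats bands must be {SAR_STAT_BANDS}")

    rx, _ = Raster(composite.bands, composite.transform).res
    factor_f = target_res / rx
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"target resolution {target_res} m is not an integer multiple of "
            f"the input {rx} m grid")

    h, w = composite.bands.shape[1:]
    out_shape = (h // factor, w // factor)
    a, b, c, d, e, f = composite.transform
    out_transform = (a * factor, b, c, d, e * factor, f)

    opt = block_mean(composite.bands, factor)
    ndvi20 = block_mean(np.asarray(ndvi_r, dtype=float), factor)
    tex20 = block_mean(np.asarray(texture_r, dtype=float), factor)
    sar20 = block_mean(sar_stats.data, factor)
    slope20 = bilinear_to(slope_r, out_shape,
                          out_transform) if slope_r.shape != out_shape else \
        slope_r.data.astype(float)

    stack = np.concatenate([opt, ndvi20[None], tex20[None], sar20, slope20[None]])
    nodata_mask = np.isnan(opt).any(axis=0)
    stack[:, nodata_mask] = np.nan
    return Raster(stack, out_transform, crs=composite.crs,
                  nodata=float("nan"), band_names=FEATURE_NAMES)
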