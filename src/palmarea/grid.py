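"""Minimal geospatial plumbing: rasters on affine grids, GeoTIFF and GeoJSON I/O.

A :class:`Raster` couples a numpy array (``(H, W)`` or ``(bands, H, W)``) with
an affine geotransform and a CRS tag, which is all the pipeline needs: every
synthetic layer lives on one projected metric grid. GeoTIFFs are written with
:mod:`tifffile`, carrying the GeoTIFF ``ModelPixelScale``/``ModelTiepoint``
tags plus a JSON sidecar tag with band names, CRS and nodata so files
round-trip losslessly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

__all__ = [
    "Raster",
    "PlacementError",
    "read_geotiff",
    "write_geotiff",
    "read_geojson",
    "write_geojson",
    "block_mean",
    "block_mode",
    "is_geographic",
    "pixel_centers",
    "contains_centers",
]

# CRS tags treated as geographic (degree units); everything else is assumed
# projected metric, which is what the synthetic generator emits.
_GEOGRAPHIC_CRS = {"EPSG:4326", "EPSG:4269", "EPSG:4267", "CRS84", "OGC:CRS84"}

#: Default projected CRS for synthetic scenes (UTM zone 47N, southern Myanmar).
DEFAULT_CRS = "EPSG:32647"


class PlacementError(RuntimeError):
    """Raised when a requested vector object cannot be placed on the landscape."""


def is_geographic(crs: str | None) -> bool:
    if crs is None:
        return False
    return crs.upper().replace(" ", "") in _GEOGRAPHIC_CRS


@dataclass
class Raster:
    """A georeferenced array.

    ``transform`` is the usual affine 6-tuple ``(a, b, c, d, e, f)`` mapping
    pixel-space ``(col, row)`` to world ``(x, y)``:

        x = a * col + b * row + c
        y = d * col + e * row + f

    with ``e`` negative for north-up grids. Pixel *centers* sit at
    ``(col + 0.5, row + 0.5)``.
    """

    data: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    crs: str = DEFAULT_CRS
    nodata: float | int | None = None
    band_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("Raster data must be 2-D or (bands, H, W) 3-D")
        self.transform = tuple(float(v) for v in self.transform)
        if self.band_names is not None:
            self.band_names = tuple(self.band_names)
            if len(self.band_names) != self.count:
                raise ValueError("band_names length does not match band count")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    @property
    def count(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    @property
    def res(self) -> tuple[float, float]:
        a, b, _, d, e, _ = self.transform
        return (math.hypot(a, d), math.hypot(b, e))

    @property
    def pixel_area_ha(self) -> float:
        rx, ry = self.res
        return rx * ry / 10_000.0

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        h, w = self.shape
        xs, ys = [], []
        for col, row in ((0, 0), (w, 0), (0, h), (w, h)):
            x, y = self.xy(row, col, offset=0.0)
            xs.append(x)
            ys.append(y)
        return min(xs), min(ys), max(xs), max(ys)

    def xy(self, row, col, offset: float = 0.5):
        """World coordinates of pixel (row, col); offset 0.5 = pixel center."""
        a, b, c, d, e, f = self.transform
        col = np.asarray(col, dtype=float) + offset
        row = np.asarray(row, dtype=float) + offset
        return a * col + b * row + c, d * col + e * row + f

    def index(self, x, y):
        """Fractional (row, col) of world coordinates (inverse transform)."""
        a, b, c, d, e, f = self.transform
        det = a * e - b * d
        x = np.asarray(x, dtype=float) - c
        y = np.asarray(y, dtype=float) - f
        col = (e * x - b * y) / det
        row = (-d * x + a * y) / det
        return row, col

    def sel(self, name: str) -> np.ndarray:
        """A single band by name (3-D rasters with band_names only)."""
        if self.band_names is None:
            raise ValueError("raster has no band names")
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise ValueError(f"band {name!r} not present") from None
        return self.data[i] if self.data.ndim == 3 else self.data

    def copy_with(self, **kw) -> "Raster":
        return replace(self, **kw)


def pixel_centers(raster: Raster) -> tuple[np.ndarray, np.ndarray]:
    """Meshgrid of world coordinates of every pixel center, shape (H, W)."""
    h, w = raster.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return raster.xy(rows, cols)


def contains_centers(geometry, raster: Raster) -> np.ndarray:
    """Boolean (H, W) mask: pixel centers falling inside ``geometry``.

    Restricted to the geometry's bounding box for speed; exact point-in-polygon
    via shapely on the candidates.
    """
    h, w = raster.shape
    out = np.zeros((h, w), dtype=bool)
    minx, miny, maxx, maxy = geometry.bounds
    corners_r, corners_c = raster.index([minx, minx, maxx, maxx], [miny, maxy, miny, maxy])
    r0 = max(0, int(np.floor(corners_r.min() - 1)))
    r1 = min(h, int(np.ceil(corners_r.max() + 1)))
    c0 = max(0, int(np.floor(corners_c.min() - 1)))
    c1 = min(w, int(np.ceil(corners_c.max() + 1)))
    if r0 >= r1 or c0 >= c1:
        return out
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    x, y = raster.xy(rows, cols)
    inside = shapely.contains_xy(geometry, x.ravel(), y.ravel()).reshape(rows.shape)
    out[r0:r1, c0:c1] = inside
    return out


# -- resampling ---------------------------------------------------------

def block_mean(data: np.ndarray, factor: int) -> np.ndarray:
    """Aggregate by non-overlapping ``factor x factor`` block means (nan-aware).

    Dimensions must be exact multiples of ``factor`` (grids are nested).
    Blocks that are entirely NaN stay NaN.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return np.asarray(data, dtype=float).copy()
    *lead, h, w = data.shape
    if h % factor or w % factor:
        raise ValueError(f"shape {(h, w)} not divisible by block factor {factor}")
    blocks = np.asarray(data, dtype=float).reshape(*lead, h // factor, factor, w // factor, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        out = np.nanmean(blocks, axis=(-3, -1))
    return out


def block_mode(data: np.ndarray, factor: int, *, nodata: int = 0) -> np.ndarray:
    """Aggregate an integer raster by block modal value (ties -> smallest label)."""
    if factor == 1:
        return np.asarray(data).copy()
    h, w = data.shape
    if h % factor or w % factor:
        raise ValueError(f"shape {(h, w)} not divisible by block factor {factor}")
    blocks = np.asarray(data).reshape(h // factor, factor, w // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(h // factor, w // factor, factor * factor)
    labels = np.unique(blocks)
    labels = labels[labels != nodata]
    counts = np.stack([(blocks == v).sum(axis=-1) for v in labels], axis=0)
    best = counts.argmax(axis=0)
    out = labels[best].astype(np.asarray(data).dtype)
    out[counts.sum(axis=0) == 0] = nodata
    return out


def bilinear_to(src: Raster, dst_shape: tuple[int, int],
                dst_transform: tuple[float, ...]) -> np.ndarray:
    """Bilinearly sample a single-band raster onto a destination grid."""
    if src.data.ndim != 2:
        raise ValueError("bilinear_to expects a single-band raster")
    h, w = dst_shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dst = Raster(np.zeros(dst_shape), dst_transform, crs=src.crs)
    x, y = dst.xy(rows, cols)
    sr, sc = src.index(x, y)
    # map_coordinates samples at array indices; centers live at index + 0.5
    coords = np.stack([sr - 0.5, sc - 0.5])
    return ndimage.map_coordinates(src.data.astype(float), coords, order=1, mode="nearest")


# -- GeoTIFF I/O --------------------------------------------------------

_GEOTIFF_META_KEY = "palmarea_meta"


def write_geotiff(path: str | Path, raster: Raster) -> Path:
    """Write a raster as a tiled GeoTIFF with pixel-scale/tiepoint geo tags."""
    path = Path(path)
    a, b, c, d, e, f = raster.transform
    meta = {
        _GEOTIFF_META_KEY: True,
        "transform": list(raster.transform),
        "crs": raster.crs,
        "nodata": raster.nodata,
        "band_names": list(raster.band_names) if raster.band_names else None,
    }
    extratags = [
        # ModelPixelScaleTag, ModelTiepointTag (GeoTIFF spec)
        (33550, "d", 3, (abs(a), abs(e), 0.0)),
        (33922, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0)),
    ]
    data = raster.data if raster.data.ndim == 3 else raster.data[None]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=extratags,
        metadata=None,
    )
    return path


def read_geotiff(path: str | Path) -> Raster:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        desc = page.description or ""
    transform = None
    crs = DEFAULT_CRS
    nodata = None
    band_names = None
    try:
        meta = json.loads(desc)
        if isinstance(meta, dict) and meta.get(_GEOTIFF_META_KEY):
            transform = tuple(meta["transform"])
            crs = meta["crs"]
            nodata = meta["nodata"]
            band_names = tuple(meta["band_names"]) if meta["band_names"] else None
    except (json.JSONDecodeError, KeyError, TypeError):
        pass
    if transform is None:
        raise ValueError(f"{path}: no georeferencing metadata found")
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    return Raster(data, transform, crs=crs, nodata=nodata, band_names=band_names)


# -- GeoJSON I/O --------------------------------------------------------

def write_geojson(path: str | Path, features: Sequence[tuple[object, Mapping]],
                  crs: str = DEFAULT_CRS) -> Path:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    path = Path(path)
    fc = {
        "type": "FeatureCollection",
        "crs_tag": crs,
        "features": [
            {"type": "Feature", "geometry": geom_mapping(geom), "properties": dict(props)}
            for geom, props in features
        ],
    }
    path.write_text(json.dumps(fc))
    return path


def read_geojson(path: str | Path) -> tuple[list[tuple[object, dict]], str]:
    doc = json.loads(Path(path).read_text())
    feats = [(geom_shape(f["geometry"]), dict(f.get("properties") or {}))
             for f in doc.get("features", [])]
    return feats, doc.get("crs_tag", DEFAULT_CRS)
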