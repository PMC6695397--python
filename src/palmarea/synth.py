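"""Synthetic landscapes with known ground truth.

Emulates the inputs of a tropical plantation-mapping study: a patchy six-class
landscape (oil palm, rubber, other trees, shrub, bare, water), a multi-date
10-band optical series with contiguous cloud blobs, a dual-polarization SAR
series with multiplicative speckle, a smooth DEM, and the vector layers
(class-labelled reference polygons; concession / district / park zones).
Everything is seeded and deterministic, so downstream stages can be tested
against exact truth without any download.

Grids mirror the mixed native resolutions of the real sensors: optical and SAR
at 10 m, the DEM at 30 m, all in one projected metric CRS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import box

from .grid import DEFAULT_CRS, PlacementError, Raster

logger = logging.getLogger(__name__)

__all__ = [
    "OPTICAL_BANDS",
    "CLASS_IDS",
    "CLASS_NAMES",
    "ClassSignature",
    "Zone",
    "SceneStack",
    "SarStack",
    "TrueLandscape",
    "default_signatures",
    "generate_class_map",
    "generate_optical_series",
    "generate_sar_series",
    "generate_ancillary",
]

#: Optical band order used throughout (Sentinel-2 classification bands).
OPTICAL_BANDS = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

CLASS_IDS = (1, 2, 3, 4, 5, 6)
CLASS_NAMES = {
    1: "oil_palm",
    2: "rubber",
    3: "other_trees",
    4: "shrub",
    5: "bare",
    6: "water",
}

OPTICAL_RES = 10.0  # m
DEM_RES = 30.0  # m

# Reflectance painted over cloud-contaminated pixels: bright and flat across
# the spectrum, with high blue and SWIR so spectral screening can find them.
_CLOUD_REFLECTANCE = np.array(
    [0.62, 0.60, 0.58, 0.57, 0.56, 0.55, 0.56, 0.55, 0.42, 0.38]
)


@dataclass(frozen=True)
class ClassSignature:
    """Spectral/backscatter fingerprint of one land-cover class.

    ``optical_means``/``optical_sd`` are per-band surface reflectances (0-1)
    over :data:`OPTICAL_BANDS`; ``sar_means``/``sar_sd`` are (VV, VH)
    backscatter in dB.
    """

    class_id: int
    optical_means: tuple[float, ...]
    optical_sd: tuple[float, ...]
    sar_means: tuple[float, float]
    sar_sd: tuple[float, float]

    def __post_init__(self) -> None:
        om = np.asarray(self.optical_means, dtype=float)
        osd = np.asarray(self.optical_sd, dtype=float)
        if om.shape != (len(OPTICAL_BANDS),) or osd.shape != om.shape:
            raise ValueError("optical signature must have one mean and SD per band")
        if om.min() < 0 or om.max() > 1:
            raise ValueError("optical means must lie in [0, 1]")
        if osd.min() < 0 or min(self.sar_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.class_id not in CLASS_IDS:
            raise ValueError(f"class_id must be one of {CLASS_IDS}")
        object.__setattr__(self, "optical_means", tuple(om))
        object.__setattr__(self, "optical_sd", tuple(osd))
        object.__setattr__(self, "sar_means", tuple(float(v) for v in self.sar_means))
        object.__setattr__(self, "sar_sd", tuple(float(v) for v in self.sar_sd))


def default_signatures(optical_sd: float = 0.012,
                       sar_sd: tuple[float, float] = (1.2, 1.5)) -> dict[int, ClassSignature]:
    """Default class signatures for the six mapped classes.

    Oil palm and rubber are deliberately close in the visible bands and
    separate mainly through the red-edge region (B5-B7, B8A) and SAR
    backscatter, mirroring why narrow red-edge bands matter for telling
    visually similar tree crops apart.
    """
    means = {
        #      B2     B3     B4     B5     B6     B7     B8     B8A    B11    B12    VV     VH
        1: (0.030, 0.060, 0.040, 0.110, 0.290, 0.340, 0.360, 0.380, 0.170, 0.085, -8.0, -14.0),
        2: (0.030, 0.062, 0.042, 0.100, 0.315, 0.370, 0.390, 0.410, 0.160, 0.080, -8.5, -14.8),
        3: (0.027, 0.055, 0.038, 0.095, 0.262, 0.312, 0.338, 0.358, 0.150, 0.075, -8.3, -14.4),
        4: (0.040, 0.078, 0.070, 0.125, 0.240, 0.275, 0.295, 0.305, 0.205, 0.130, -9.9, -15.9),
        5: (0.056, 0.093, 0.096, 0.145, 0.228, 0.255, 0.275, 0.285, 0.228, 0.158, -10.6, -16.7),
        6: (0.060, 0.050, 0.030, 0.025, 0.020, 0.018, 0.015, 0.012, 0.005, 0.003, -17.0, -24.0),
    }
    sigs = {}
    for cid, row in means.items():
        sigs[cid] = ClassSignature(
            class_id=cid,
            optical_means=row[:10],
            optical_sd=(optical_sd,) * 10,
            sar_means=row[10:],
            sar_sd=sar_sd,
        )
    return sigs


@dataclass
class Zone:
    """A named accounting polygon: concession, district, or park."""

    zone_id: str
    kind: str
    geometry: object

    KINDS = ("concession", "district", "park")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"zone kind must be one of {self.KINDS}, got {self.kind!r}")
        if not self.geometry.is_valid:
            raise ValueError(f"zone {self.zone_id}: invalid geometry")


@dataclass
class SceneStack:
    """Multi-date optical series: bands (T, 10, H, W), qa_mask (T, H, W) bool."""

    dates: list[str]
    bands: np.ndarray
    qa_mask: np.ndarray
    transform: tuple[float, ...]
    crs: str = DEFAULT_CRS
    nodata: float = float("nan")
    band_names: tuple[str, ...] = OPTICAL_BANDS

    def __post_init__(self) -> None:
        t = len(self.dates)
        if self.bands.shape[:2] != (t, len(self.band_names)):
            raise ValueError("bands must be (n_dates, n_bands, H, W)")
        if self.qa_mask.shape != (t, *self.bands.shape[2:]):
            raise ValueError("qa_mask must be congruent with bands")

    def scene(self, t: int) -> dict[str, np.ndarray]:
        """Named single-date bands, for cloud screening."""
        return {name: self.bands[t, i] for i, name in enumerate(self.band_names)}


@dataclass
class SarStack:
    """Multi-date SAR series in dB: vv and vh each (T, H, W)."""

    dates: list[str]
    vv: np.ndarray
    vh: np.ndarray
    transform: tuple[float, ...]
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if self.vv.shape != self.vh.shape or self.vv.shape[0] != len(self.dates):
            raise ValueError("vv/vh must be congruent (n_dates, H, W) arrays")


@dataclass
class TrueLandscape:
    """Ground truth bundle: class map, DEM, zones, labelled reference polygons."""

    class_map: Raster
    dem: Raster
    zones: list[Zone]
    reference_polygons: list[tuple[object, int]] = field(default_factory=list)


# ----------------------------------------------------------------------
# class map

def _make_transform(height: int, width: int, res: float) -> tuple[float, ...]:
    # north-up grid with the origin at the top-left corner, y increasing north
    return (res, 0.0, 0.0, 0.0, -res, height * res)


def generate_class_map(width: int, height: int,
                       class_weights: Sequence[float],
                       patch_scale: float = 8.0,
                       seed: int = 0,
                       block: int = 2) -> Raster:
    """Spatially autocorrelated 6-class truth raster on a 10 m grid.

    A Gaussian-smoothed random field is thresholded at the empirical quantiles
    of the cumulative class weights, producing contiguous patches whose
    frequencies match ``class_weights`` (exactly up to quantile granularity).

    ``block`` sets the granularity of stand boundaries in pixels: the field is
    generated on a ``block``-times-coarser grid and replicated, so land-cover
    patches are unions of ``block x block`` management blocks (the default 2
    aligns stand edges with the 20 m analysis grid — plantation stands are
    management units, and this keeps the ground truth unambiguous at the
    analysis resolution). ``block=1`` gives per-pixel boundaries.
    """
    if width <= 0 or height <= 0:
        raise ValueError("raster dimensions must be positive")
    if patch_scale < 1:
        raise ValueError("patch_scale must be >= 1 pixel")
    if block < 1 or width % block or height % block:
        raise ValueError("block must be >= 1 and divide both dimensions")
    w = np.asarray(class_weights, dtype=float)
    if w.shape != (len(CLASS_IDS),):
        raise ValueError(f"class_weights must have {len(CLASS_IDS)} entries")
    if w.min() < 0 or not np.isfinite(w).all() or w.sum() <= 0:
        raise ValueError("class_weights must be non-negative and normalizable")
    w = w / w.sum()

    rng = np.random.default_rng(seed)
    ch, cw = height // block, width // block
    fld = ndimage.gaussian_filter(rng.standard_normal((ch, cw)),
                                  patch_scale / block)
    cum = np.cumsum(w)[:-1]
    thresholds = np.quantile(fld, cum)
    classes = np.searchsorted(thresholds, fld, side="left").astype(np.uint8) + 1
    if block > 1:
        classes = np.kron(classes, np.ones((block, block), dtype=np.uint8))
    return Raster(classes, _make_transform(height, width, OPTICAL_RES),
                  crs=DEFAULT_CRS, nodata=0)


# ----------------------------------------------------------------------
# optical series

def _unit_smooth_field(shape: tuple[int, ...], scale: float,
                       rng: np.random.Generator, df: float = 3.0) -> np.ndarray:
    """Stand-scale random field(s), unit variance, heavy-tailed.

    One Student-t draw (``df`` degrees of freedom) per ``scale``-sized cell,
    replicated over the cell and lightly smoothed — each management block has
    its own condition offset, with occasional extreme stands (burned shrub,
    flooded bare ground, anomalous canopies) that Gaussian tails would make
    vanishingly rare. Smoothing is over the trailing two (spatial) axes;
    leading axes index independent fields.
    """
    *lead, h, w = shape
    cell = max(1, int(round(scale)))
    ch, cw = -(-h // cell), -(-w // cell)
    coarse = rng.standard_t(df, size=(*lead, ch, cw))
    fld = np.kron(coarse, np.ones((cell, cell)))[..., :h, :w]
    sigma = [0] * len(lead) + [cell / 6.0, cell / 6.0]
    fld = ndimage.gaussian_filter(fld, sigma)
    sd = fld.std(axis=(-2, -1), keepdims=True)
    sd[sd == 0] = 1.0
    return fld / sd


def _cloud_blobs(shape: tuple[int, int], fraction: float, blob_scale: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Contiguous cloud mask covering exactly ``fraction`` of the scene."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    fld = ndimage.gaussian_filter(rng.standard_normal(shape), blob_scale)
    return fld >= np.quantile(fld, 1.0 - fraction)


def generate_optical_series(truth: Raster,
                            signatures: Mapping[int, ClassSignature],
                            n_dates: int = 8,
                            cloud_fraction: float = 0.3,
                            seed: int = 0,
                            cloud_blob_scale: float = 12.0,
                            static_frac: float = 0.12,
                            stand_frac: float = 0.02,
                            stand_scale: float = 20.0,
                            static_floor: float = 0.02,
                            dates: Sequence[str] | None = None) -> SceneStack:
    """Per-date 10-band reflectance images from class signatures + noise.

    Each pixel's underlying reflectance is the class signature times a
    date-independent pixel effect — the within-class heterogeneity of real
    landscapes that temporal compositing cannot average away. The effect has
    two components per band: an i.i.d. part (``static_frac``: canopy texture)
    and a spatially smooth part (``stand_frac`` at correlation length
    ``stand_scale`` pixels: stand age, soil and moisture gradients that shift
    whole stands coherently). Per-date noise (``optical_sd``) sits on top. A
    ``cloud_fraction`` share of each date is overwritten with bright cloud
    reflectance (contiguous blobs) and flagged in ``qa_mask``.
    """
    present = np.unique(truth.data)
    missing = [int(c) for c in present if c != 0 and int(c) not in signatures]
    if missing:
        raise ValueError(f"no signature for classes {missing}")
    if not 0 <= cloud_fraction <= 1:
        raise ValueError("cloud_fraction must be in [0, 1]")
    if n_dates < 1:
        raise ValueError("n_dates must be >= 1")

    h, wdt = truth.shape
    nb = len(OPTICAL_BANDS)
    mean_img = np.zeros((nb, h, wdt))
    sd_img = np.zeros((nb, h, wdt))
    for cid, sig in signatures.items():
        m = truth.data == cid
        for b in range(nb):
            mean_img[b][m] = sig.optical_means[b]
            sd_img[b][m] = sig.optical_sd[b]

    rng = np.random.default_rng(seed)
    if static_frac < 0 or stand_frac < 0:
        raise ValueError("static_frac and stand_frac must be >= 0")
    pixel_effect = 1.0 + static_frac * rng.standard_normal((nb, h, wdt))
    if stand_frac > 0:
        pixel_effect += stand_frac * _unit_smooth_field((nb, h, wdt), stand_scale, rng)
    base_img = mean_img * pixel_effect
    if static_floor > 0:
        # additive floor: heterogeneity that does not scale with brightness,
        # so dark classes (water) are not noise-free
        base_img = base_img + static_floor * _unit_smooth_field(
            (nb, h, wdt), stand_scale, rng)
    bands = np.empty((n_dates, nb, h, wdt), dtype=np.float32)
    qa = np.empty((n_dates, h, wdt), dtype=bool)
    for t in range(n_dates):
        img = base_img + rng.standard_normal((nb, h, wdt)) * sd_img
        mask = _cloud_blobs((h, wdt), cloud_fraction, cloud_blob_scale, rng)
        cloudy = _CLOUD_REFLECTANCE[:, None] + 0.02 * rng.standard_normal((nb, mask.sum()))
        img[:, mask] = cloudy
        bands[t] = np.clip(img, 0.0, 1.0)
        qa[t] = mask
    date_labels = list(dates) if dates is not None else [f"d{t:02d}" for t in range(n_dates)]
    return SceneStack(date_labels, bands, qa, truth.transform, crs=truth.crs)


# ----------------------------------------------------------------------
# SAR series

def generate_sar_series(truth: Raster,
                        signatures: Mapping[int, ClassSignature],
                        n_dates: int = 8,
                        seed: int = 0,
                        static_db: float = 1.0,
                        stand_db: float = 0.25,
                        stand_scale: float = 20.0) -> SarStack:
    """Dual-pol backscatter series with multiplicative speckle.

    Speckle is lognormal in linear power — equivalently additive Gaussian in
    dB — so the temporal dB mean is an unbiased estimate of each pixel's
    underlying backscatter. This models the residual variability of
    multi-looked GRD scenes rather than single-look gamma speckle. As with
    the optical generator, a date-independent pixel effect — i.i.d.
    (``static_db``) plus spatially smooth (``stand_db`` at ``stand_scale``
    pixels) — carries the within-class structural heterogeneity that temporal
    averaging cannot remove.
    """
    present = np.unique(truth.data)
    missing = [int(c) for c in present if c != 0 and int(c) not in signatures]
    if missing:
        raise ValueError(f"no signature for classes {missing}")
    if n_dates < 1:
        raise ValueError("n_dates must be >= 1")

    h, w = truth.shape
    mean_db = np.zeros((2, h, w))
    sd_db = np.zeros((2, h, w))
    for cid, sig in signatures.items():
        m = truth.data == cid
        for p in range(2):
            mean_db[p][m] = sig.sar_means[p]
            sd_db[p][m] = sig.sar_sd[p]

    if static_db < 0 or stand_db < 0:
        raise ValueError("static_db and stand_db must be >= 0")
    rng = np.random.default_rng(seed)
    pixel_effect = static_db * rng.standard_normal((2, h, w))
    if stand_db > 0:
        pixel_effect += stand_db * _unit_smooth_field((2, h, w), stand_scale, rng)
    noise = rng.standard_normal((n_dates, 2, h, w))
    db = (mean_db + pixel_effect)[None] + noise * sd_db[None]
    return SarStack([f"d{t:02d}" for t in range(n_dates)],
                    vv=db[:, 0].astype(np.float32),
                    vh=db[:, 1].astype(np.float32),
                    transform=truth.transform, crs=truth.crs)


# ----------------------------------------------------------------------
# DEM, zones, reference polygons

def _smooth_dem(shape: tuple[int, int], rng: np.random.Generator,
                base: float = 150.0, relief: float = 350.0) -> np.ndarray:
    h, w = shape
    rough = ndimage.gaussian_filter(rng.standard_normal(shape), max(4, min(h, w) // 8))
    rough = rough / (np.abs(rough).max() or 1.0)
    yy, xx = np.mgrid[0:h, 0:w]
    trend = 0.3 * (xx / max(w - 1, 1)) + 0.2 * (yy / max(h - 1, 1))
    dem = base + relief * (0.5 * (rough + 1.0) * 0.7 + trend * 0.3)
    return dem.astype(np.float32)


def _random_box(extent: tuple[float, float, float, float], rng: np.random.Generator,
                frac_lo: float = 0.15, frac_hi: float = 0.40):
    minx, miny, maxx, maxy = extent
    spanx, spany = maxx - minx, maxy - miny
    wdt = rng.uniform(frac_lo, frac_hi) * spanx
    hgt = rng.uniform(frac_lo, frac_hi) * spany
    x0 = rng.uniform(minx, maxx - wdt)
    y0 = rng.uniform(miny, maxy - hgt)
    return box(x0, y0, x0 + wdt, y0 + hgt)


def generate_ancillary(truth: Raster,
                       n_concessions: int = 3,
                       n_reference_polygons_per_class: "int | Mapping[int, int]" = 5,
                       seed: int = 0,
                       n_districts: int = 2,
                       n_parks: int = 1,
                       flat_dem: bool = False,
                       reference_patch_px: int = 3) -> TrueLandscape:
    """DEM, zone polygons, and pure single-class reference polygons.

    The DEM is a sum of low-frequency surfaces on a 30 m grid (or constant
    when ``flat_dem``). Districts partition the extent into equal-width
    strips; concessions and parks are random rectangles that may overlap
    (concessions may overlap parks, as real concession grants do). Reference
    polygons are small squares drawn entirely inside single-class patches, so
    rasterizing them against the truth yields exactly one label each.
    """
    if isinstance(n_reference_polygons_per_class, Mapping):
        per_class = {cid: int(n_reference_polygons_per_class.get(cid, 0))
                     for cid in CLASS_IDS}
    else:
        per_class = {cid: int(n_reference_polygons_per_class) for cid in CLASS_IDS}
    if n_concessions < 1 or min(per_class.values()) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = truth.shape
    extent = truth.bounds

    # DEM on its own coarser grid covering the same extent
    dem_h = max(2, int(round(h * OPTICAL_RES / DEM_RES)))
    dem_w = max(2, int(round(w * OPTICAL_RES / DEM_RES)))
    if flat_dem:
        dem_data = np.full((dem_h, dem_w), 200.0, dtype=np.float32)
    else:
        dem_data = _smooth_dem((dem_h, dem_w), rng)
    dem = Raster(dem_data, _make_transform(dem_h, dem_w, DEM_RES), crs=truth.crs)

    zones: list[Zone] = []
    minx, miny, maxx, maxy = extent
    step = (maxx - minx) / n_districts
    for i in range(n_districts):
        geom = box(minx + i * step, miny, minx + (i + 1) * step, maxy)
        zones.append(Zone(f"district_{i + 1}", "district", geom))
    for i in range(n_concessions):
        zones.append(Zone(f"concession_{i + 1}", "concession", _random_box(extent, rng)))
    for i in range(n_parks):
        zones.append(Zone(f"park_{i + 1}", "park", _random_box(extent, rng, 0.20, 0.45)))

    # reference polygons: squares of reference_patch_px pixels per side placed
    # where an eroded class mask guarantees purity
    # erode by exactly the polygon footprint: polygons stay single-class but
    # may extend to stand edges, keeping the sample representative of the map
    half = reference_patch_px // 2
    erosion = np.ones((reference_patch_px, reference_patch_px), dtype=bool)
    ref_polys: list[tuple[object, int]] = []
    for cid in CLASS_IDS:
        mask = truth.data == cid
        if not mask.any():
            raise PlacementError(
                f"class {CLASS_NAMES[cid]} absent from the landscape; "
                "cannot place reference polygons")
        core = ndimage.binary_erosion(mask, structure=erosion)
        # restrict candidate centers to a separation lattice so polygons of
        # one class cannot overlap (each contributes distinct pixels)
        lattice = np.zeros_like(core)
        stride = reference_patch_px + 1
        off = int(rng.integers(stride))
        lattice[off::stride, off::stride] = True
        rows, cols = np.nonzero(core & lattice)
        if rows.size < per_class[cid]:
            raise PlacementError(
                f"landscape too fragmented to place "
                f"{per_class[cid]} reference polygons for class "
                f"{CLASS_NAMES[cid]} (only {rows.size} candidate centers)")
        pick = rng.choice(rows.size, size=per_class[cid], replace=False)
        for k in pick:
            r, c = int(rows[k]), int(cols[k])
            # box spanning reference_patch_px whole pixels, snapped to edges
            x0, y0 = truth.xy(r + half + 1, c - half, offset=0.0)
            x1, y1 = truth.xy(r - half, c + half + 1, offset=0.0)
            ref_polys.append((box(x0, y0, x1, y1), cid))

    return TrueLandscape(class_map=truth, dem=dem, zones=zones,
                         reference_polygons=ref_polys)
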