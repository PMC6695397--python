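"""Cloud screening and temporal compositing.

Reduces the multi-date stacks to single analysis rasters: a per-pixel cloud
mask per date, a percentile-window mean composite of the optical series, and
temporal mean/SD statistics of the SAR series.

The composite statistic is the mean of all clear observations whose value
falls inside the [p_lo, p_hi] percentile interval of the per-pixel series —
a trimmed mean that discards residual cloud (bright) and shadow (dark)
outliers that per-date screening missed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grid import Raster
from .synth import SarStack, SceneStack

logger = logging.getLogger(__name__)

__all__ = [
    "CloudRule",
    "Composite",
    "detect_clouds",
    "percentile_mean_composite",
    "sar_temporal_stats",
]

SAR_STAT_BANDS = ("VV_mean", "VV_sd", "VH_mean", "VH_sd")


@dataclass(frozen=True)
class CloudRule:
    """Spectral cloud screening thresholds (reflectance, 0-1 scale).

    A pixel is cloudy iff the QA mask says so, OR it is simultaneously bright
    in blue (B2) and SWIR (B11), OR its cirrus band (B10) exceeds
    ``cirrus_threshold``. The cirrus test runs only when a threshold is set,
    since cirrus is an atmospheric band that classification stacks usually do
    not carry. ``nir_floor`` > 0 additionally requires B8 brightness for the
    blue+SWIR test, guarding against flagging dark water.
    """

    blue_threshold: float = 0.25
    swir_threshold: float = 0.20
    cirrus_threshold: float | None = None
    nir_floor: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.blue_threshold, self.swir_threshold, self.nir_floor]
        if self.cirrus_threshold is not None:
            vals.append(self.cirrus_threshold)
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("cloud thresholds must lie in [0, 1]")


@dataclass
class Composite:
    """Cloud-free composite: 10 bands plus a per-pixel clear-observation count."""

    bands: np.ndarray  # (10, H, W), NaN where nodata
    valid_obs: np.ndarray  # (H, W) int
    transform: tuple[float, ...]
    crs: str
    band_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.bands.shape[0] != len(self.band_names):
            raise ValueError("band count does not match band_names")
        if self.valid_obs.shape != self.bands.shape[1:]:
            raise ValueError("valid_obs must be congruent with bands")

    def sel(self, name: str) -> np.ndarray:
        return self.bands[self.band_names.index(name)]

    def as_raster(self) -> Raster:
        return Raster(self.bands, self.transform, crs=self.crs,
                      nodata=float("nan"), band_names=self.band_names)


def detect_clouds(scene: Mapping[str, np.ndarray],
                  rule: CloudRule = CloudRule(),
                  qa_mask: np.ndarray | None = None) -> np.ndarray:
    """Boolean cloud mask for one date: QA mask OR spectral brightness tests."""

    def band(name: str) -> np.ndarray:
        if name not in scene:
            raise ValueError(f"cloud screening requires band {name}")
        return np.asarray(scene[name])

    blue = band("B2")
    swir = band("B11")
    cloudy = (blue > rule.blue_threshold) & (swir > rule.swir_threshold)
    if rule.nir_floor > 0:
        cloudy &= band("B8") >= rule.nir_floor
    if rule.cirrus_threshold is not None:
        cloudy |= band("B10") > rule.cirrus_threshold
    if qa_mask is not None:
        qa = np.asarray(qa_mask, dtype=bool)
        if qa.shape != cloudy.shape:
            raise ValueError("qa_mask shape does not match scene bands")
        cloudy |= qa
    return cloudy


def percentile_mean_composite(stack: SceneStack,
                              cloud_masks: np.ndarray | Sequence[np.ndarray],
                              p_lo: float = 40.0,
                              p_hi: float = 60.0,
                              min_obs: int = 3) -> Composite:
    """Mean of clear observations inside the per-pixel percentile window.

    Per pixel and band: the [p_lo, p_hi] percentile bounds of the clear series
    are computed with linear interpolation, and all observations inside the
    closed interval are averaged. If the interpolated interval captures no
    observation, the single observation nearest the series median is used
    instead of leaving a hole. Pixels with fewer than ``min_obs`` clear
    observations are nodata; ``valid_obs`` records the clear count either way.
    """
    if not 0 <= p_lo < p_hi <= 100:
        raise ValueError("require 0 <= p_lo < p_hi <= 100")
    if len(stack.dates) == 0:
        raise ValueError("empty scene stack")
    masks = np.asarray(cloud_masks, dtype=bool)
    if masks.shape != stack.qa_mask.shape:
        raise ValueError("cloud_masks must be (n_dates, H, W)")

    x = stack.bands.astype(np.float64)  # (T, B, H, W)
    clear = ~masks
    x = np.where(clear[:, None], x, np.nan)
    valid_obs = clear.sum(axis=0).astype(np.int32)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(x, p_lo, axis=0)
        hi = np.nanpercentile(x, p_hi, axis=0)
        inside = (x >= lo[None]) & (x <= hi[None])
        n_in = inside.sum(axis=0)
        total = np.where(inside, x, 0.0).sum(axis=0)
        out = np.divide(total, n_in, out=np.full(lo.shape, np.nan), where=n_in > 0)

        # interpolated bounds can exclude every observation; fall back to the
        # clear observation nearest the series median
        hole = (n_in == 0) & (valid_obs[None] > 0)
        if hole.any():
            med = np.nanmedian(x, axis=0)
            dist = np.abs(x - med[None])
            dist = np.where(np.isnan(dist), np.inf, dist)
            nearest = np.take_along_axis(
                x, dist.argmin(axis=0)[None], axis=0)[0]
            out = np.where(hole, nearest, out)

    out[:, valid_obs < min_obs] = np.nan
    return Composite(out, valid_obs, stack.transform, stack.crs, stack.band_names)


def sar_temporal_stats(stack: SarStack) -> Raster:
    """Temporal mean and population SD of VV and VH, in dB.

    Returns a 4-band raster (VV_mean, VV_sd, VH_mean, VH_sd); a single-date
    stack yields SD 0 everywhere.
    """
    if len(stack.dates) < 1:
        raise ValueError("SAR stack must contain at least one date")
    vv = stack.vv.astype(np.float64)
    vh = stack.vh.astype(np.float64)
    data = np.stack([
        vv.mean(axis=0),
        vv.std(axis=0),  # population SD (ddof=0)
        vh.mean(axis=0),
        vh.std(axis=0),
    ])
    return Raster(data, stack.transform, crs=stack.crs,
                  nodata=float("nan"), band_names=SAR_STAT_BANDS)
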