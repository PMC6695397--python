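"""Zonal accounting: per-zone class areas, concession shares, emissions.

Pixels belong to a zone iff their center lies inside the zone geometry
(pixel-count basis, matching the area estimator). Overlapping zones of
different kinds each receive the pixel; overlapping zones of the same kind
are unioned before kind-level totals so nothing is double-counted within a
kind. The emissions calculator converts an at-risk area and an aboveground
carbon density into CO2-equivalent mass via the 44/12 molar-mass ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.validation import make_valid

from .grid import Raster, contains_centers
from .synth import CLASS_IDS, CLASS_NAMES, Zone
from .train import NODATA_CLASS

logger = logging.getLogger(__name__)

__all__ = [
    "EmissionsEstimate",
    "zonal_class_areas",
    "kind_class_areas",
    "concession_shares",
    "inside_outside_split",
    "emissions",
    "acres_to_hectares",
]

HA_PER_ACRE = 0.40468564224
CO2_PER_C = 44.0 / 12.0


def _clean_geometry(zone: Zone):
    geom = zone.geometry
    if not geom.is_valid:
        repaired = make_valid(geom)
        if repaired.is_valid and not repaired.is_empty:
            logger.warning("zone %s: repaired invalid geometry", zone.zone_id)
            return repaired
        raise ValueError(f"zone {zone.zone_id}: invalid geometry beyond repair")
    return geom


def _class_counts(class_map: Raster, mask: np.ndarray) -> np.ndarray:
    vals = class_map.data[mask]
    return np.array([(vals == c).sum() for c in CLASS_IDS], dtype=np.int64)


def zonal_class_areas(class_map: Raster, zones: Sequence[Zone],
                      pixel_area: float | None = None) -> pd.DataFrame:
    """Per-zone per-class pixel counts, areas (ha), and within-zone shares.

    Shares use the zone's mapped (non-nodata) pixel total as denominator.
    A zone containing no pixel centers is reported with zeros and a warning.
    """
    if pixel_area is None:
        pixel_area = class_map.pixel_area_ha
    rows = []
    for zone in zones:
        geom = _clean_geometry(zone)
        mask = contains_centers(geom, class_map)
        mask &= class_map.data != NODATA_CLASS
        counts = _class_counts(class_map, mask)
        total = counts.sum()
        if total == 0:
            logger.warning("zone %s (%s) covers no mapped pixel centers",
                           zone.zone_id, zone.kind)
        for cid, cnt in zip(CLASS_IDS, counts):
            rows.append({
                "zone_id": zone.zone_id,
                "kind": zone.kind,
                "class_id": cid,
                "class_name": CLASS_NAMES[cid],
                "pixel_count": int(cnt),
                "area_ha": cnt * pixel_area,
                "share": cnt / total if total > 0 else 0.0,
            })
    return pd.DataFrame(rows)


def kind_class_areas(class_map: Raster, zones: Sequence[Zone], kind: str,
                     pixel_area: float | None = None) -> pd.Series:
    """Class areas (ha) within the union of all zones of one kind.

    Same-kind overlaps are unioned first, so each pixel is counted once.
    """
    if pixel_area is None:
        pixel_area = class_map.pixel_area_ha
    geoms = [_clean_geometry(z) for z in zones if z.kind == kind]
    if not geoms:
        raise ValueError(f"no zones of kind {kind!r}")
    union = shapely.union_all(geoms)
    mask = contains_centers(union, class_map)
    mask &= class_map.data != NODATA_CLASS
    counts = _class_counts(class_map, mask)
    names = [CLASS_NAMES[c] for c in CLASS_IDS]
    return pd.Series(counts * pixel_area, index=names, name=f"{kind}_area_ha")


def concession_shares(areas_by_class: Mapping[str, float] | pd.Series) -> pd.Series:
    """Percent of the total concession area occupied by each class.

    The denominator is the sum over all six classes within concessions.
    Rounding is left to the report layer (the conventional print is nearest
    percent).
    """
    s = pd.Series(areas_by_class, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("concession class areas sum to zero")
    return 100.0 * s / total


def inside_outside_split(total_area: Mapping[str, float] | pd.Series,
                         concession_area: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """Split per-class totals into inside- and outside-concession parts.

    ``outside = total - inside``; a negative outside (inside exceeding the
    class total) indicates inconsistent inputs and is an error.
    """
    total = pd.Series(total_area, dtype=float)
    inside = pd.Series(concession_area, dtype=float).reindex(total.index).fillna(0.0)
    outside = total - inside
    bad = outside.index[outside < -1e-9].tolist()
    if bad:
        raise ValueError(
            f"inside-concession area exceeds class total for: {', '.join(map(str, bad))}")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * inside / total, np.nan)
    return pd.DataFrame({
        "total_ha": total,
        "inside_ha": inside,
        "outside_ha": outside,
        "inside_pct": pct,
    })


@dataclass(frozen=True)
class EmissionsEstimate:
    """CO2-equivalent emissions from clearing an area of standing biomass."""

    area_ha: float
    carbon_density: float  # Mg C / ha (aboveground)
    conversion_factor: float  # mass ratio CO2 / C
    co2e_tg: float


def emissions(area_ha: float, carbon_density: float,
              conversion: float = CO2_PER_C) -> EmissionsEstimate:
    """Tg CO2e released by clearing ``area_ha`` at the given carbon density.

    co2e [Tg] = area [ha] * density [Mg C/ha] * conversion [CO2/C] * 1e-6.
    The default conversion is the exact molar-mass ratio 44/12; belowground
    and soil pools are not included.
    """
    if area_ha < 0 or carbon_density < 0 or conversion < 0:
        raise ValueError("emissions inputs must be non-negative")
    co2e_tg = area_ha * carbon_density * conversion * 1e-6
    return EmissionsEstimate(area_ha, carbon_density, conversion, co2e_tg)


def acres_to_hectares(acres: float) -> float:
    """Exact acre -> hectare conversion (1 ac = 0.40468564224 ha)."""
    return acres * HA_PER_ACRE
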