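"""Reference sampling, Random-Forest classification, and majority filtering.

Reference polygons are rasterized by pixel-center membership on the 20 m
analysis grid; the samples are split 50/50 per class (stratified by class,
polygon provenance retained), a 100-tree Random Forest with 4 variables per
split (~sqrt(17)) is fitted, the map is predicted per pixel, and a 3x3
majority (mode) filter removes salt-and-pepper speckle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES
from .grid import Raster
from .synth import CLASS_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "extract_reference_pixels",
    "split_reference",
    "train_classifier",
    "predict_map",
    "majority_filter",
]

#: Integer code for unclassified / nodata pixels in class maps.
NODATA_CLASS = 0

SAMPLE_INDEX_COLUMNS = ["row", "col", "class_id", "polygon_id"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Random-Forest hyperparameters: 100 trees, 4 variables per node."""

    n_trees: int = 100
    m_try: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.m_try <= len(FEATURE_NAMES):
            raise ValueError(f"m_try must be in [1, {len(FEATURE_NAMES)}]")


def extract_reference_pixels(polygons, stack: Raster) -> pd.DataFrame:
    """One sample per analysis pixel whose center falls inside a polygon.

    ``polygons`` is an iterable of ``(geometry, class_id)``. Returns a tidy
    frame with grid indices, label, polygon provenance, and the 17 feature
    values. Pixels with non-finite features (nodata in the stack) are dropped
    with a logged count; a polygon covering no pixel center contributes zero
    samples and logs a warning.
    """
    if stack.band_names is None or tuple(stack.band_names) != FEATURE_NAMES:
        raise ValueError("stack must carry the 17 named feature layers")
    h, w = stack.shape
    records: list[pd.DataFrame] = []
    n_dropped = 0
    for pid, (geom, class_id) in enumerate(polygons):
        minx, miny, maxx, maxy = geom.bounds
        rr, cc = stack.index(np.array([minx, maxx]), np.array([miny, maxy]))
        r0, r1 = int(np.floor(rr.min())) - 1, int(np.ceil(rr.max())) + 1
        c0, c1 = int(np.floor(cc.min())) - 1, int(np.ceil(cc.max())) + 1
        r0, r1 = max(0, r0), min(h, r1)
        c0, c1 = max(0, c0), min(w, c1)
        if r0 >= r1 or c0 >= c1:
            logger.warning("polygon %d (class %s) lies outside the raster; 0 samples",
                           pid, CLASS_NAMES.get(class_id, class_id))
            continue
        rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        x, y = stack.xy(rows, cols)
        inside = shapely.contains_xy(geom, x.ravel(), y.ravel()).reshape(rows.shape)
        if not inside.any():
            logger.warning("polygon %d (class %s) covers no pixel centers; 0 samples",
                           pid, CLASS_NAMES.get(class_id, class_id))
            continue
        r_in, c_in = rows[inside], cols[inside]
        feats = stack.data[:, r_in, c_in].T  # (n, 17)
        finite = np.isfinite(feats).all(axis=1)
        n_dropped += int((~finite).sum())
        df = pd.DataFrame(feats[finite], columns=list(FEATURE_NAMES))
        df.insert(0, "polygon_id", pid)
        df.insert(0, "class_id", int(class_id))
        df.insert(0, "col", c_in[finite])
        df.insert(0, "row", r_in[finite])
        records.append(df)
    if n_dropped:
        logger.info("dropped %d reference pixels with nodata features", n_dropped)
    if not records:
        return pd.DataFrame(columns=SAMPLE_INDEX_COLUMNS + list(FEATURE_NAMES))
    out = pd.concat(records, ignore_index=True)
    # overlapping polygons can claim the same pixel; keep the first claim so a
    # pixel can never appear on both sides of the train/test split
    n_before = len(out)
    out = out.drop_duplicates(subset=["row", "col"], keep="first", ignore_index=True)
    if len(out) < n_before:
        logger.info("dropped %d duplicate pixels claimed by overlapping polygons",
                    n_before - len(out))
    return out


def split_reference(samples: pd.DataFrame, fraction: float = 0.5,
                    seed: int = 0, unit: str = "pixel") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-class random split into (train, test).

    With ``unit="pixel"``, floor(fraction * n) pixels per class go to
    training and the remainder to testing. With ``unit="polygon"``, whole
    polygons are assigned to one side (floor rule on the polygon count per
    class) — a cluster-aware split that stops spatially autocorrelated
    within-polygon pixels from leaking between training and testing. Either
    way the partition is disjoint, exhaustive, and seeded.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if unit not in ("pixel", "polygon"):
        raise ValueError("unit must be 'pixel' or 'polygon'")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cid, grp in samples.groupby("class_id"):
        if unit == "polygon":
            polys = grp["polygon_id"].unique()
            if len(polys) < 2:
                raise ValueError(
                    f"class {CLASS_NAMES.get(cid, cid)} has only {len(polys)} "
                    "polygon(s); need at least 2 for a polygon-level split")
            perm_p = rng.permutation(polys)
            k = int(np.floor(fraction * len(polys)))
            in_train = grp["polygon_id"].isin(perm_p[:k])
            train_idx.append(grp.index.to_numpy()[in_train])
            test_idx.append(grp.index.to_numpy()[~in_train])
            continue
        n = len(grp)
        if n < 2:
            raise ValueError(
                f"class {CLASS_NAMES.get(cid, cid)} has only {n} sample(s); "
                "need at least 2 to split")
        perm = rng.permutation(grp.index.to_numpy())
        k = int(np.floor(fraction * n))
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    train = samples.loc[np.concatenate(train_idx)].copy()
    test = samples.loc[np.concatenate(test_idx)].copy()
    train["role"] = "train"
    test["role"] = "test"
    return train.reset_index(drop=True), test.reset_index(drop=True)


def train_classifier(train: pd.DataFrame,
                     spec: ClassifierSpec = ClassifierSpec()) -> RandomForestClassifier:
    """Fit the Random Forest over the 17 predictors."""
    classes = train["class_id"].unique()
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    X = train[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y = train["class_id"].to_numpy(dtype=np.int64)
    model = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.m_try,
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    model.feature_names_ordered_ = tuple(FEATURE_NAMES)
    return model


def predict_map(model: RandomForestClassifier, stack: Raster,
                chunk_rows: int = 256) -> Raster:
    """Per-pixel class prediction; nodata feature pixels map to class 0."""
    expected = getattr(model, "feature_names_ordered_", tuple(FEATURE_NAMES))
    if stack.band_names is None or tuple(stack.band_names) != tuple(expected):
        raise ValueError(f"stack layers must match training order {expected}")
    h, w = stack.shape
    out = np.full((h, w), NODATA_CLASS, dtype=np.uint8)
    for r0 in range(0, h, chunk_rows):
        r1 = min(h, r0 + chunk_rows)
        block = stack.data[:, r0:r1, :].reshape(stack.count, -1).T
        finite = np.isfinite(block).all(axis=1)
        if finite.any():
            pred = model.predict(block[finite])
            flat = out[r0:r1].reshape(-1)
            flat[finite] = pred.astype(np.uint8)
            out[r0:r1] = flat.reshape(r1 - r0, w)
    return Raster(out, stack.transform, crs=stack.crs, nodata=NODATA_CLASS)


def majority_filter(class_map: Raster, window: int = 3) -> Raster:
    """Modal-class smoothing over a square neighbourhood.

    Each pixel takes the modal class of its window, counting only in-bounds,
    non-nodata pixels; if the center's own class ties the maximum vote, the
    center keeps its class (deterministic, conservative). Nodata pixels stay
    nodata and cast no votes. A class absent from the window can never be
    introduced.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    data = class_map.data
    present = [int(c) for c in np.unique(data) if c != NODATA_CLASS]
    if not present:
        return class_map.copy_with(data=data.copy())
    votes = np.stack([
        ndimage.uniform_filter((data == c).astype(np.float64), size=window,
                               mode="constant", cval=0.0) * window**2
        for c in present
    ])
    votes = np.round(votes).astype(np.int32)
    best = votes.max(axis=0)
    winner = np.asarray(present, dtype=data.dtype)[votes.argmax(axis=0)]
    out = winner.copy()
    # ties (or outright wins) involving the center's own class keep the center
    keep = np.zeros(data.shape, dtype=bool)
    for i, c in enumerate(present):
        keep |= (data == c) & (votes[i] == best)
    out[keep] = data[keep]
    out[data == NODATA_CLASS] = NODATA_CLASS
    return class_map.copy_with(data=out)
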