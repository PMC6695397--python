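"""Accuracy assessment and stratified error-adjusted area estimation.

The confusion (error) matrix counts test pixels by mapped class i (rows) and
reference class j (columns). Map accuracy is summarized by overall, user's
(1 - commission) and producer's (1 - omission) accuracy. Class areas are then
estimated with the standard stratified estimator that treats the mapped
classes as strata:

    W_i     = N_i / sum_i N_i            (mapped-area stratum weights)
    p_hat_ij = W_i * n_ij / n_i.
    p_hat_.j = sum_i p_hat_ij            (bias-corrected area proportion)
    A_hat_j  = p_hat_.j * A_total
    SE(p_hat_.j) = sqrt( sum_i W_i^2 * q_ij (1 - q_ij) / (n_i. - 1) ),
                   q_ij = n_ij / n_i.
    CI_j     = A_hat_j +/- z * SE * A_total      (z = 1.96 for 95%)

This corrects the raw pixel-count areas for classification bias using the
reference sample and attaches defensible confidence intervals. A Monte-Carlo
coverage check of those intervals is included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Raster
from .synth import CLASS_IDS, CLASS_NAMES
from .train import NODATA_CLASS

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorMatrix",
    "AccuracyMetrics",
    "CoverageResult",
    "error_matrix",
    "accuracy_metrics",
    "error_adjusted_areas",
    "coverage_simulation",
]

Z_95 = 1.96


@dataclass
class ErrorMatrix:
    """Confusion counts plus the mapped pixel totals needed for area estimation.

    ``counts[i, j]`` is the number of test pixels mapped as class ``ids[i]``
    with reference label ``ids[j]`` — rows are the map, columns the reference.
    ``mapped_pixels[i]`` is N_i, the total filtered-map pixel count of class
    ``ids[i]``; ``pixel_area`` is in hectares.
    """

    counts: np.ndarray
    mapped_pixels: np.ndarray
    pixel_area: float
    ids: tuple[int, ...] = CLASS_IDS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.mapped_pixels = np.asarray(self.mapped_pixels, dtype=np.int64)
        k = len(self.ids)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if self.mapped_pixels.shape != (k,):
            raise ValueError("mapped_pixels must have one entry per class")
        if (self.counts < 0).any() or (self.mapped_pixels < 0).any():
            raise ValueError("counts and pixel totals must be non-negative")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")

    @property
    def total_area_ha(self) -> float:
        return float(self.mapped_pixels.sum()) * self.pixel_area

    def to_frame(self) -> pd.DataFrame:
        names = [CLASS_NAMES.get(c, str(c)) for c in self.ids]
        df = pd.DataFrame(self.counts,
                          index=pd.Index(names, name="mapped"),
                          columns=pd.Index(names, name="reference"))
        df["mapped_pixels"] = self.mapped_pixels
        return df

    def to_csv(self, path: str | Path) -> None:
        meta = pd.DataFrame({"pixel_area_ha": [self.pixel_area]})
        with open(path, "w") as fh:
            self.to_frame().to_csv(fh)
            meta.to_csv(fh, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pixel_area: float) -> "ErrorMatrix":
        name_to_id = {v: k for k, v in CLASS_NAMES.items()}
        ids = tuple(name_to_id.get(n, n) for n in df.index)
        counts = df.drop(columns="mapped_pixels").to_numpy()
        return cls(counts, df["mapped_pixels"].to_numpy(), pixel_area, ids=ids)


def error_matrix(test_samples: pd.DataFrame, class_map: Raster,
                 pixel_area: float | None = None) -> ErrorMatrix:
    """Cross-tabulate test pixels (reference labels) against the filtered map.

    Test pixels falling on nodata map cells are excluded with a logged count;
    mapped pixel totals N_i come from the full map.
    """
    if pixel_area is None:
        pixel_area = class_map.pixel_area_ha
    rows = test_samples["row"].to_numpy(dtype=np.intp)
    cols = test_samples["col"].to_numpy(dtype=np.intp)
    ref = test_samples["class_id"].to_numpy(dtype=np.int64)
    mapped = class_map.data[rows, cols].astype(np.int64)

    usable = mapped != NODATA_CLASS
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("excluded %d test pixels on nodata map cells", n_excluded)

    k = len(CLASS_IDS)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (mapped[usable] - 1, ref[usable] - 1), 1)
    mapped_pixels = np.array([(class_map.data == c).sum() for c in CLASS_IDS],
                             dtype=np.int64)
    return ErrorMatrix(counts, mapped_pixels, pixel_area)


@dataclass
class AccuracyMetrics:
    """Overall, per-class user's and producer's accuracy.

    ``overall`` is the plain sample-count version; ``overall_area_weighted``
    weights each mapped stratum by its map share W_i. Classes with an empty
    row/column have NaN (undefined, not zero) UA/PA.
    """

    overall: float
    overall_area_weighted: float
    users: pd.Series
    producers: pd.Series


def accuracy_metrics(m: ErrorMatrix) -> AccuracyMetrics:
    counts = m.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("error matrix has no samples")
    diag = np.diag(counts)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(row_sums > 0, diag / row_sums, np.nan)
        pa = np.where(col_sums > 0, diag / col_sums, np.nan)
    overall = float(diag.sum() / total)

    weights = m.mapped_pixels / m.mapped_pixels.sum()
    strata = (m.mapped_pixels > 0) & (row_sums > 0)
    overall_w = float((weights[strata] * ua[strata]).sum())

    names = [CLASS_NAMES.get(c, str(c)) for c in m.ids]
    return AccuracyMetrics(
        overall=overall,
        overall_area_weighted=overall_w,
        users=pd.Series(ua, index=names, name="users_accuracy"),
        producers=pd.Series(pa, index=names, name="producers_accuracy"),
    )


def error_adjusted_areas(m: ErrorMatrix, z: float = Z_95) -> pd.DataFrame:
    """Bias-corrected class areas with standard errors and confidence intervals.

    Returns one row per reference class with columns ``p_hat`` (estimated
    area proportion), ``area_ha``, ``se_ha``, ``ci_lo_ha``, ``ci_hi_ha``.
    Stratum weights W_i are attached as ``df.attrs["stratum_weights"]``.
    Strata (mapped classes) with zero map pixels drop out with weight 0; a
    stratum that is mapped but has <= 1 test sample is an error, because its
    variance contribution is undefined.
    """
    n_total = m.mapped_pixels.sum()
    if n_total <= 0:
        raise ValueError("no mapped pixels")
    weights = m.mapped_pixels / n_total
    row_sums = m.counts.sum(axis=1)

    bad = [CLASS_NAMES.get(m.ids[i], str(m.ids[i]))
           for i in range(len(m.ids)) if weights[i] > 0 and row_sums[i] <= 1]
    if bad:
        raise ValueError(
            f"strata with <= 1 test sample (variance undefined): {', '.join(bad)}")

    k = len(m.ids)
    q = np.zeros((k, k))
    active = row_sums > 0
    q[active] = m.counts[active] / row_sums[active, None]

    p_hat = weights @ q  # p_hat_.j
    a_total = m.total_area_ha
    area = p_hat * a_total

    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = weights[:, None] ** 2 * q * (1 - q) / (row_sums[:, None] - 1)
    se_p = np.sqrt(var_terms[active].sum(axis=0))
    se_ha = se_p * a_total

    names = [CLASS_NAMES.get(c, str(c)) for c in m.ids]
    df = pd.DataFrame({
        "p_hat": p_hat,
        "area_ha": area,
        "se_ha": se_ha,
        "ci_lo_ha": area - z * se_ha,
        "ci_hi_ha": area + z * se_ha,
    }, index=pd.Index(names, name="class"))
    df.attrs["stratum_weights"] = pd.Series(weights, index=names, name="W")
    df.attrs["z"] = z
    df.attrs["total_area_ha"] = a_total
    return df


@dataclass
class CoverageResult:
    """Per-class empirical CI coverage from the Monte-Carlo check."""

    coverage: pd.Series
    mean_ci_width: pd.Series
    reps: int
    degenerate: bool = False


def coverage_simulation(true_proportions, confusion, n_test: int = 500,
                        reps: int = 1000, seed: int = 0,
                        z: float = Z_95) -> CoverageResult:
    """Empirical coverage of the area CIs under a known confusion model.

    ``true_proportions[j]`` are the true class area proportions;
    ``confusion[j, i]`` is P(mapped as i | true class j), a row-stochastic
    matrix. Each rep draws a stratified test sample (allocation proportional
    to mapped shares, at least 2 per stratum), runs the estimator, and checks
    whether each class's CI contains its true area. A zero-confusion
    (identity) model yields zero-width intervals and trivially full coverage;
    that case is flagged ``degenerate``.
    """
    t = np.asarray(true_proportions, dtype=float)
    C = np.asarray(confusion, dtype=float)
    k = t.size
    if C.shape != (k, k):
        raise ValueError("confusion must be square and match true_proportions")
    if not np.allclose(C.sum(axis=1), 1.0):
        raise ValueError("confusion rows must sum to 1")
    if reps < 100:
        raise ValueError("reps must be >= 100 for a meaningful coverage estimate")
    t = t / t.sum()

    joint = t[:, None] * C  # P(true j, mapped i)
    w = joint.sum(axis=0)  # mapped shares W_i
    degenerate = bool(np.allclose(np.diag(C), 1.0))

    active = w > 0
    ref_given_map = np.zeros((k, k))
    ref_given_map[:, active] = joint[:, active] / w[active]

    # fixed proportional allocation, at least 2 per active stratum
    n_i = np.zeros(k, dtype=int)
    n_i[active] = np.maximum(2, np.round(n_test * w[active]).astype(int))

    a_total = 1.0  # work on the proportion scale
    weights = w  # mapped shares are known exactly in the simulated landscape

    rng = np.random.default_rng(seed)
    # draws[r, i, j]: reference-label counts of stratum i in rep r
    draws = np.zeros((reps, k, k), dtype=np.int64)
    for i in range(k):
        if n_i[i] > 0:
            draws[:, i, :] = rng.multinomial(n_i[i], ref_given_map[:, i].T, size=reps)

    q = np.zeros((reps, k, k))
    nz = n_i > 0
    q[:, nz, :] = draws[:, nz, :] / n_i[nz][None, :, None]
    p_hat = np.einsum("i,rij->rj", weights, q)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = weights[None, :, None] ** 2 * q * (1 - q) / (n_i[None, :, None] - 1)
    se = np.sqrt(var_terms[:, nz, :].sum(axis=1))

    lo = p_hat - z * se
    hi = p_hat + z * se
    true_area = t * a_total
    inside = (lo <= true_area[None]) & (true_area[None] <= hi)
    names = [CLASS_NAMES.get(c, str(c)) for c in CLASS_IDS[:k]] if k == len(CLASS_IDS) \
        else [f"class_{j + 1}" for j in range(k)]
    return CoverageResult(
        coverage=pd.Series(inside.mean(axis=0), index=names, name="coverage"),
        mean_ci_width=pd.Series((hi - lo).mean(axis=0), index=names, name="ci_width"),
        reps=reps,
        degenerate=degenerate,
    )
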