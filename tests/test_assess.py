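import numpy as np
import pandas as pd
import pytest

from palmarea.assess import (
    ErrorMatrix,
    accuracy_metrics,
    coverage_simulation,
    error_adjusted_areas,
    error_matrix,
)
from palmarea.grid import Raster
from palmarea.train import NODATA_CLASS


def _class_map(data, res=20.0):
    h, w = np.asarray(data).shape
    return Raster(np.asarray(data, np.uint8), (res, 0, 0, 0, -res, h * res),
                  nodata=NODATA_CLASS)


def _test_samples(rows, cols, labels):
    return pd.DataFrame({"row": rows, "col": cols, "class_id": labels})


def stratified_estimator_oracle(counts, mapped_pixels, pixel_area, z=1.96):
    """Independent brute-force implementation: explicit loops, no vectorization."""
    counts = np.asarray(counts, float)
    k = counts.shape[0]
    N = np.asarray(mapped_pixels, float)
    W = N / N.sum()
    a_total = N.sum() * pixel_area
    out = []
    for j in range(k):
        p = 0.0
        var = 0.0
        for i in range(k):
            n_i = counts[i].sum()
            if n_i == 0:
                continue
            q = counts[i, j] / n_i
            p += W[i] * q
            var += W[i] ** 2 * q * (1 - q) / (n_i - 1)
        se = np.sqrt(var)
        out.append((p, p * a_total, se * a_total,
                    (p - z * se) * a_total, (p + z * se) * a_total))
    return np.array(out)


class TestErrorMatrix:
    def test_perfect_map_is_diagonal(self):
        data = np.tile(np.arange(1, 7), (6, 1))
        cmap = _class_map(data)
        rows, cols = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        samples = _test_samples(rows.ravel(), cols.ravel(),
                                data[rows.ravel(), cols.ravel()])
        m = error_matrix(samples, cmap)
        assert (m.counts == np.diag(np.full(6, 6))).all()

    def test_total_conservation(self):
        rng = np.random.default_rng(0)
        data = rng.integers(1, 7, (10, 10))
        cmap = _class_map(data)
        rows = rng.integers(0, 10, 40)
        cols = rng.integers(0, 10, 40)
        labels = rng.integers(1, 7, 40)
        m = error_matrix(_test_samples(rows, cols, labels), cmap)
        assert m.counts.sum() == 40

    def test_nodata_cells_excluded(self, caplog):
        data = np.full((4, 4), 2)
        data[0, 0] = NODATA_CLASS
        m = error_matrix(_test_samples([0, 1], [0, 1], [2, 2]), _class_map(data))
        assert m.counts.sum() == 1

    def test_corruption_rate_recovery(self):
        # plant 10% label corruption: off-diagonal share within +/-0.03 of 0.10
        rng = np.random.default_rng(42)
        truth = rng.integers(1, 7, (60, 60))
        mapped = truth.copy()
        corrupt = rng.random(truth.shape) < 0.10
        shift = rng.integers(1, 6, truth.shape)
        mapped[corrupt] = (truth[corrupt] - 1 + shift[corrupt]) % 6 + 1
        rows, cols = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
        samples = _test_samples(rows.ravel(), cols.ravel(), truth.ravel())
        m = error_matrix(samples, _class_map(mapped))
        off_diag = 1.0 - np.trace(m.counts) / m.counts.sum()
        assert off_diag == pytest.approx(0.10, abs=0.03)

    def test_mapped_pixels_from_full_map(self):
        data = np.repeat(np.arange(1, 7), 6).reshape(6, 6)
        m = error_matrix(_test_samples([0], [0], [1]), _class_map(data))
        assert (m.mapped_pixels == 6).all()

    def test_csv_roundtrip(self, tmp_path):
        m = ErrorMatrix(np.diag([3, 4, 5, 6, 7, 8]),
                        [10, 20, 30, 40, 50, 60], 0.04)
        frame = m.to_frame()
        back = ErrorMatrix.from_frame(frame, 0.04)
        np.testing.assert_array_equal(back.counts, m.counts)
        np.testing.assert_array_equal(back.mapped_pixels, m.mapped_pixels)


class TestAccuracyMetrics:
    def test_identity_matrix_all_ones(self):
        m = ErrorMatrix(np.eye(6, dtype=int) * 10, [100] * 6, 0.04)
        acc = accuracy_metrics(m)
        assert acc.overall == 1.0
        assert acc.overall_area_weighted == pytest.approx(1.0)
        assert (acc.users == 1.0).all() and (acc.producers == 1.0).all()

    def test_two_class_hand_arithmetic(self):
        counts = np.zeros((6, 6), int)
        counts[0, 0], counts[0, 1] = 45, 5
        counts[1, 0], counts[1, 1] = 10, 40
        m = ErrorMatrix(counts, [60, 40, 0, 0, 0, 0], 1.0)
        acc = accuracy_metrics(m)
        assert acc.overall == pytest.approx(0.85)
        assert acc.users.iloc[0] == pytest.approx(0.90)
        assert acc.producers.iloc[0] == pytest.approx(45 / 55)

    def test_uniform_matrix_over_k(self):
        m = ErrorMatrix(np.full((6, 6), 5), [10] * 6, 1.0)
        assert accuracy_metrics(m).overall == pytest.approx(1 / 6)

    def test_empty_class_reported_missing_not_zero(self):
        counts = np.zeros((6, 6), int)
        counts[:2, :2] = [[8, 2], [1, 9]]
        m = ErrorMatrix(counts, [50, 50, 0, 0, 0, 0], 1.0)
        acc = accuracy_metrics(m)
        assert np.isnan(acc.users.iloc[2])
        assert np.isnan(acc.producers.iloc[5])


class TestErrorAdjustedAreas:
    def test_perfect_classification(self):
        m = ErrorMatrix(np.diag([10] * 6), [100, 200, 300, 150, 150, 100], 0.5)
        est = error_adjusted_areas(m)
        np.testing.assert_allclose(est["area_ha"],
                                   np.array([100, 200, 300, 150, 150, 100]) * 0.5)
        np.testing.assert_allclose(est["se_ha"], 0.0)

    def test_two_stratum_worked_case_matches_oracle(self):
        # W = (0.6, 0.4), rows (45,5)/50 and (10,40)/50, A_total 1000 ha
        counts = np.zeros((6, 6), int)
        counts[0, :2] = [45, 5]
        counts[1, :2] = [10, 40]
        m = ErrorMatrix(counts, [600, 400, 0, 0, 0, 0], 1.0)
        est = error_adjusted_areas(m, z=1.96)
        oracle = stratified_estimator_oracle(counts, m.mapped_pixels, 1.0)
        np.testing.assert_allclose(est["area_ha"], oracle[:, 1], atol=0.01)
        np.testing.assert_allclose(est["se_ha"], oracle[:, 2], atol=0.01)
        np.testing.assert_allclose(est["ci_lo_ha"], oracle[:, 3], atol=0.01)
        # frozen hand-computed values for the two mapped classes
        assert est["area_ha"].iloc[0] == pytest.approx(620.0, abs=0.01)
        assert est["area_ha"].iloc[1] == pytest.approx(380.0, abs=0.01)
        assert est["se_ha"].iloc[0] == pytest.approx(34.4046, abs=0.001)
        assert est["ci_lo_ha"].iloc[0] == pytest.approx(620 - 1.96 * 34.4046, abs=0.01)

    def test_area_conservation_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            counts = rng.integers(0, 50, (6, 6))
            counts += np.eye(6, dtype=int) * 2  # ensure n_i >= 2
            mapped = rng.integers(1, 10_000, 6)
            m = ErrorMatrix(counts, mapped, 0.04)
            est = error_adjusted_areas(m)
            assert est["area_ha"].sum() == pytest.approx(m.total_area_ha, rel=1e-9)
            assert est["p_hat"].sum() == pytest.approx(1.0, rel=1e-9)
            assert (est["ci_lo_ha"] <= est["area_ha"] + 1e-9).all()
            assert (est["area_ha"] <= est["ci_hi_ha"] + 1e-9).all()

    def test_se_zero_iff_pure_strata(self):
        counts = np.diag([5, 5, 5, 5, 5, 5])
        m = ErrorMatrix(counts, [10] * 6, 1.0)
        assert (error_adjusted_areas(m)["se_ha"] == 0).all()
        counts2 = counts.copy()
        counts2[0, 1] = 2
        m2 = ErrorMatrix(counts2, [10] * 6, 1.0)
        assert error_adjusted_areas(m2)["se_ha"].iloc[1] > 0

    def test_within_stratum_scaling_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 20, (6, 6))
        mapped = rng.integers(100, 1000, 6)
        a = error_adjusted_areas(ErrorMatrix(counts, mapped, 1.0))
        b = error_adjusted_areas(ErrorMatrix(counts * 3, mapped, 1.0))
        np.testing.assert_allclose(a["p_hat"], b["p_hat"])

    def test_unsampled_mapped_stratum_rejected(self):
        counts = np.diag([5, 5, 5, 5, 5, 0])
        m = ErrorMatrix(counts, [10] * 6, 1.0)
        with pytest.raises(ValueError, match="water"):
            error_adjusted_areas(m)

    def test_unmapped_class_estimated_from_other_strata(self):
        # water never mapped (N=0) but appears in reference labels
        counts = np.diag([10, 10, 10, 10, 10, 0])
        counts[4, 5] = 2  # bare stratum contains true water
        m = ErrorMatrix(counts, [100, 100, 100, 100, 100, 0], 1.0)
        est = error_adjusted_areas(m)
        assert est["area_ha"].loc["water"] > 0


class TestCoverageSimulation:
    def test_zero_confusion_degenerate(self):
        res = coverage_simulation(np.full(6, 1 / 6), np.eye(6), n_test=300,
                                  reps=200, seed=0)
        assert res.degenerate
        assert (res.coverage == 1.0).all()
        np.testing.assert_allclose(res.mean_ci_width, 0.0)

    def test_moderate_confusion_near_nominal(self):
        C = np.full((6, 6), 0.02)
        np.fill_diagonal(C, 0.90)
        t = np.array([0.15, 0.15, 0.30, 0.20, 0.12, 0.08])
        res = coverage_simulation(t, C, n_test=500, reps=400, seed=1)
        assert (res.coverage > 0.90).all()

    def test_width_scales_inverse_sqrt_n(self):
        C = np.full((6, 6), 0.02)
        np.fill_diagonal(C, 0.90)
        t = np.full(6, 1 / 6)
        w1 = coverage_simulation(t, C, n_test=500, reps=300, seed=2).mean_ci_width
        w2 = coverage_simulation(t, C, n_test=1000, reps=300, seed=3).mean_ci_width
        ratio = (w1 / w2).mean()
        assert ratio == pytest.approx(np.sqrt(2), rel=0.2)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError, match="reps"):
            coverage_simulation(np.full(6, 1 / 6), np.eye(6), reps=50)

    def test_bad_confusion_rejected(self):
        C = np.full((6, 6), 0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            coverage_simulation(np.full(6, 1 / 6), C, reps=100)
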