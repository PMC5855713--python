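import numpy as np
import pytest

from oximap.calibrate import CalibrationMatrix
from oximap.camera import CalibrationStateError, RgbImage
from oximap.imaging import (
    NormalizationError,
    ParameterMaps,
    Roi,
    RoiBoundsError,
    RoiSeries,
    derive_saturation,
    estimate_maps,
    relative_change,
    roi_timecourse,
)

COEF = np.array(
    [[1.0, 2.0, 1.4], [10.0, -5.0, 0.2], [-8.0, 12.0, -0.1], [3.0, 1.0, 0.05]]
)
MATRIX = CalibrationMatrix(
    coefficients=COEF, diagnostics={}, provenance={"camera_hash": "x"}
)


def _calibrated(data, t=None):
    return RgbImage(np.asarray(data, dtype=float), calibration="reflectance", time_s=t)


class TestEstimateMaps:
    def test_uniform_image_gives_uniform_maps(self):
        img = _calibrated(np.full((5, 7, 3), 0.3))
        maps = estimate_maps(img, MATRIX)
        for plane in (maps.c_hbo, maps.c_hbr, maps.b):
            assert np.ptp(plane) == 0.0

    def test_matches_explicit_matrix_vector_product(self):
        rgb = np.array([0.2, 0.5, 0.1])
        img = _calibrated(rgb.reshape(1, 1, 3))
        maps = estimate_maps(img, MATRIX)
        x = np.array([1.0, *rgb])
        expected = np.array([x @ COEF[:, k] for k in range(3)])  # independent product
        np.testing.assert_allclose(
            [maps.c_hbo[0, 0], maps.c_hbr[0, 0], maps.b[0, 0]], expected, rtol=1e-14
        )

    def test_commutes_with_cropping(self):
        rng = np.random.default_rng(0)
        img = _calibrated(rng.random((8, 9, 3)))
        full = estimate_maps(img, MATRIX)
        crop = estimate_maps(_calibrated(img.data[2:6, 3:8]), MATRIX)
        np.testing.assert_array_equal(full.c_hbo[2:6, 3:8], crop.c_hbo)
        np.testing.assert_array_equal(full.b[2:6, 3:8], crop.b)

    def test_affine_in_the_image(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((6, 6, 3)), rng.random((6, 6, 3))
        alpha = 0.3
        mixed = estimate_maps(_calibrated(alpha * a + (1 - alpha) * b), MATRIX)
        m_a = estimate_maps(_calibrated(a), MATRIX)
        m_b = estimate_maps(_calibrated(b), MATRIX)
        np.testing.assert_allclose(
            mixed.c_hbr, alpha * m_a.c_hbr + (1 - alpha) * m_b.c_hbr, rtol=1e-10
        )

    def test_negative_estimates_preserved_and_flagged(self):
        img = _calibrated(np.array([[[1.0, 0.0, 1.0]]]))  # drives c_hbr negative
        maps = estimate_maps(img, MATRIX)
        assert maps.c_hbr[0, 0] < 0
        assert maps.flagged["c_hbr_negative"] == 1

    def test_uncalibrated_image_rejected(self):
        with pytest.raises(CalibrationStateError):
            estimate_maps(RgbImage(np.ones((2, 2, 3)), calibration="raw"), MATRIX)


class TestDeriveSaturation:
    def test_eq_arithmetic(self):
        out = derive_saturation(
            ParameterMaps(
                c_hbo=np.array([[2.0, 3.0, 5.0]]),
                c_hbr=np.array([[2.0, 1.0, 0.0]]),
                b=np.ones((1, 3)),
            )
        )
        np.testing.assert_array_equal(out.c_hbt, [[4.0, 4.0, 5.0]])
        np.testing.assert_allclose(out.sto2, [[50.0, 75.0, 100.0]])
        np.testing.assert_array_equal(out.c_hbt, out.c_hbo + out.c_hbr)

    def test_sto2_bounded_for_nonnegative_inputs(self):
        rng = np.random.default_rng(2)
        maps = ParameterMaps(
            c_hbo=rng.random((10, 10)), c_hbr=rng.random((10, 10)), b=np.ones((10, 10))
        )
        out = derive_saturation(maps)
        valid = ~out.invalid
        assert np.all(out.sto2[valid] >= 0.0)
        assert np.all(out.sto2[valid] <= 100.0)

    def test_vanishing_total_marked_invalid(self):
        maps = ParameterMaps(
            c_hbo=np.zeros((2, 2)), c_hbr=np.zeros((2, 2)), b=np.ones((2, 2))
        )
        out = derive_saturation(maps)
        assert out.invalid.all()
        assert np.isnan(out.sto2).all()

    def test_display_clipping_is_opt_in(self):
        maps = ParameterMaps(
            c_hbo=np.array([[5.0]]), c_hbr=np.array([[-1.0]]), b=np.ones((1, 1))
        )
        raw = derive_saturation(maps)
        assert raw.sto2[0, 0] > 100.0
        clipped = derive_saturation(maps, clip_display=True)
        assert clipped.sto2[0, 0] == 100.0


def _map_stack(planes, times):
    return [
        derive_saturation(
            ParameterMaps(c_hbo=p, c_hbr=np.ones_like(p), b=np.ones_like(p), time_s=t)
        )
        for p, t in zip(planes, times)
    ]


class TestRoiTimecourse:
    def test_single_pixel_roi_equals_pixel_trace(self):
        rng = np.random.default_rng(3)
        planes = [rng.random((4, 4)) for _ in range(5)]
        stack = _map_stack(planes, range(1, 6))
        series = roi_timecourse(stack, Roi(2, 1, 1, 1), "c_hbo")
        np.testing.assert_allclose(series.values, [p[1, 2] for p in planes])

    def test_uniform_plane_and_window_mean(self):
        plane = np.array([[1.0, 2.0], [3.0, 4.0]])
        stack = _map_stack([plane], [0.0])
        series = roi_timecourse(stack, Roi(0, 0, 2, 2), "c_hbo")
        assert series.values[0] == 2.5
        const = _map_stack([np.full((3, 3), 7.0)], [0.0])
        assert roi_timecourse(const, Roi(0, 0, 3, 3), "c_hbo").values[0] == 7.0

    def test_out_of_bounds_roi_rejected(self):
        stack = _map_stack([np.ones((4, 4))], [0.0])
        with pytest.raises(RoiBoundsError):
            roi_timecourse(stack, Roi(2, 2, 4, 4), "c_hbo")

    def test_frame_order_permutation_then_sort_restores_series(self):
        rng = np.random.default_rng(4)
        planes = [rng.random((3, 3)) for _ in range(6)]
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        stack = _map_stack(planes, times)
        series = roi_timecourse(stack, Roi(0, 0, 3, 3), "c_hbo")
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = [stack[i] for i in perm]
        restored = sorted(shuffled, key=lambda m: m.time_s)
        series2 = roi_timecourse(restored, Roi(0, 0, 3, 3), "c_hbo")
        np.testing.assert_array_equal(series.values, series2.values)
        np.testing.assert_array_equal(series.times, series2.times)


class TestRelativeChange:
    def _series(self, values, times=None):
        values = np.asarray(values, dtype=float)
        times = np.arange(1.0, values.size + 1) if times is None else np.asarray(times)
        return RoiSeries(times=times, values=values, roi=Roi(0, 0, 1, 1), signal="c_hbt")

    def test_identities(self):
        s = self._series([2.0, 2.0, 4.0, 1.0])
        out = relative_change(s, (1.0, 2.0))
        np.testing.assert_allclose(out.values, [0.0, 0.0, 1.0, -0.5])

    def test_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(1, 2, 8)
        s1 = relative_change(self._series(vals), (1.0, 3.0))
        s2 = relative_change(self._series(7.3 * vals), (1.0, 3.0))
        np.testing.assert_allclose(s1.values, s2.values, rtol=1e-12)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(NormalizationError):
            relative_change(self._series([0.0, 0.0, 1.0]), (1.0, 2.0))

    def test_empty_control_window_rejected(self):
        with pytest.raises(NormalizationError):
            relative_change(self._series([1.0, 2.0]), (10.0, 20.0))

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        s = self._series([1.0, 2.0, 3.0])
        s.to_csv(tmp_path / "tc.csv")
        df = pd.read_csv(tmp_path / "tc.csv")
        assert list(df.columns) == ["time_s", "value"]
        np.testing.assert_array_equal(df["value"].to_numpy(), s.values)
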