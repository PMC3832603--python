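import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oecfkit import OECFDataset, fixtures
from oecfkit.bezier import (
    LUT,
    BezierCurve,
    build_lut,
    eval_bezier,
    fit_bezier,
    fit_bezier_segments,
    load_bezier_curve,
    load_lut,
    lut_lookup,
    save_bezier_curve,
    save_lut,
)
from oecfkit.errors import BelowRangeError, DataError, LUTError


def de_casteljau(curve, t):
    """Independent evaluation oracle by repeated linear interpolation."""
    pts = list(zip(curve.control_x, curve.control_y))
    while len(pts) > 1:
        pts = [
            ((1 - t) * a[0] + t * b[0], (1 - t) * a[1] + t * b[1])
            for a, b in zip(pts[:-1], pts[1:])
        ]
    return pts[0]


class TestEvalBezier:
    def test_t0_is_p0(self, known_curve):
        x, y = eval_bezier(known_curve, 0.0)
        assert (x, y) == (known_curve.control_x[0], known_curve.control_y[0])

    def test_t1_is_p3(self, known_curve):
        x, y = eval_bezier(known_curve, 1.0)
        assert (x, y) == (known_curve.control_x[3], known_curve.control_y[3])

    def test_red_fixture_endpoints(self):
        curve = fixtures.fixture_bezier("canon40d_red")
        assert eval_bezier(curve, 1.0)[1] == pytest.approx(0.962, abs=1e-12)
        assert eval_bezier(curve, 0.0)[1] == pytest.approx(0.220, abs=1e-12)

    def test_midpoint_formula(self, known_curve):
        x, y = eval_bezier(known_curve, 0.5)
        cx, cy = known_curve.control_x, known_curve.control_y
        assert x == pytest.approx((cx[0] + 3 * cx[1] + 3 * cx[2] + cx[3]) / 8)
        assert y == pytest.approx((cy[0] + 3 * cy[1] + 3 * cy[2] + cy[3]) / 8)

    @given(
        t=st.floats(0, 1),
        coords=st.lists(st.floats(-1, 2), min_size=8, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_de_casteljau(self, t, coords):
        curve = BezierCurve(control_x=coords[:4], control_y=coords[4:])
        x, y = eval_bezier(curve, t)
        ox, oy = de_casteljau(curve, t)
        assert x == pytest.approx(ox, abs=1e-12)
        assert y == pytest.approx(oy, abs=1e-12)

    @given(
        t=st.floats(0, 1),
        coords=st.lists(st.floats(-1, 2), min_size=8, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_convex_hull_property(self, t, coords):
        curve = BezierCurve(control_x=coords[:4], control_y=coords[4:])
        x, y = eval_bezier(curve, t)
        assert curve.control_x.min() - 1e-12 <= x <= curve.control_x.max() + 1e-12
        assert curve.control_y.min() - 1e-12 <= y <= curve.control_y.max() + 1e-12

    def test_t_out_of_range(self, known_curve):
        with pytest.raises(ValueError):
            eval_bezier(known_curve, 1.2)


class TestFitBezier:
    def test_exact_recovery(self, known_curve, curve_dataset):
        fit = fit_bezier(curve_dataset)
        np.testing.assert_allclose(
            fit.control_x, known_curve.control_x, atol=1e-6
        )
        np.testing.assert_allclose(
            fit.control_y, known_curve.control_y, atol=1e-6
        )

    def test_endpoints_pinned(self, curve_dataset):
        fit = fit_bezier(curve_dataset)
        ds = curve_dataset.sorted_by_exposure()
        assert fit.control_x[0] == ds.exposure[0]
        assert fit.control_y[0] == ds.response[0]
        assert fit.control_x[3] == ds.exposure[-1]
        assert fit.control_y[3] == ds.response[-1]

    def test_collinear_data_gives_chord(self):
        x = np.linspace(0.1, 0.9, 12)
        y = 0.15 + 0.8 * (x - 0.1)
        ds = OECFDataset("line", x, y, normalised=True, e_max=1.0)
        fit = fit_bezier(ds)
        ts = np.linspace(0, 1, 257)
        bx, by = eval_bezier(fit, ts)
        chord = 0.15 + 0.8 * (bx - 0.1)
        assert np.max(np.abs(by - chord)) < 1e-9

    def test_unnormalised_input_raises(self):
        ds = OECFDataset("x", [1e-4, 2e-4, 3e-4, 4e-4],
                         [10.0, 50.0, 100.0, 200.0])
        with pytest.raises(DataError):
            fit_bezier(ds)

    def test_too_few_points(self):
        ds = OECFDataset("x", [0.1, 0.2, 0.3], [0.1, 0.2, 0.3],
                         normalised=True)
        with pytest.raises(DataError):
            fit_bezier(ds)

    def test_sse_attached_and_small_on_exact_data(self, curve_dataset):
        fit = fit_bezier(curve_dataset)
        assert fit.sse is not None
        assert fit.sse < 1e-16

    def test_without_correction_still_reasonable(self, curve_dataset,
                                                 known_curve):
        fit = fit_bezier(curve_dataset, parameter_correction=False)
        np.testing.assert_allclose(
            fit.control_x, known_curve.control_x, atol=0.05
        )


class TestFitBezierSegments:
    def test_single_segment_equals_fit_bezier(self, curve_dataset):
        single = fit_bezier(curve_dataset)
        segs = fit_bezier_segments(curve_dataset, 1)
        assert len(segs) == 1
        np.testing.assert_allclose(segs[0].control_x, single.control_x)
        np.testing.assert_allclose(segs[0].control_y, single.control_y)

    def test_two_generators_recovered(self):
        left = BezierCurve(control_x=[0.0, 0.1, 0.3, 0.5],
                           control_y=[0.0, 0.3, 0.4, 0.5])
        right = BezierCurve(control_x=[0.5, 0.7, 0.9, 1.0],
                            control_y=[0.5, 0.6, 0.9, 0.95])
        ts = np.linspace(0, 1, 15)
        lx, ly = eval_bezier(left, ts)
        rx, ry = eval_bezier(right, ts)
        x = np.concatenate([lx, rx[1:]])
        y = np.concatenate([ly, ry[1:]])
        ds = OECFDataset("two", x, y, normalised=True, e_max=1.0)
        segs = fit_bezier_segments(ds, 2)
        np.testing.assert_allclose(segs[0].control_x, left.control_x, atol=1e-6)
        np.testing.assert_allclose(segs[1].control_y, right.control_y, atol=1e-6)

    def test_c0_continuity(self, noisy_red_dataset, red_e_max):
        ds = noisy_red_dataset
        ds.e_max = red_e_max * 1.2
        from oecfkit import normalise_dataset

        norm = normalise_dataset(ds)
        segs = fit_bezier_segments(norm, 3)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.control_x[3] == b.control_x[0]
            assert a.control_y[3] == b.control_y[0]

    def test_too_many_segments(self, curve_dataset):
        with pytest.raises(DataError):
            fit_bezier_segments(curve_dataset, 8)

    def test_zero_segments(self, curve_dataset):
        with pytest.raises(ValueError):
            fit_bezier_segments(curve_dataset, 0)


class TestBuildLut:
    def test_default_length_256(self, known_curve):
        assert len(build_lut(known_curve)) == 256

    def test_first_entry_is_swapped_p0(self, known_curve):
        lut = build_lut(known_curve)
        assert lut.response[0] == known_curve.control_y[0]
        assert lut.exposure[0] == known_curve.control_x[0]

    def test_straight_line_identity(self):
        line = BezierCurve(control_x=[0, 1 / 3, 2 / 3, 1.0],
                           control_y=[0, 1 / 3, 2 / 3, 1.0])
        lut = build_lut(line)
        np.testing.assert_allclose(lut.exposure, lut.response, atol=1e-12)

    def test_non_monotone_y_raises(self):
        wiggle = BezierCurve(control_x=[0, 0.3, 0.7, 1.0],
                             control_y=[0.0, 1.5, -0.5, 1.0])
        with pytest.raises(LUTError):
            build_lut(wiggle)

    def test_non_monotone_x_fixture_raises(self):
        curve = fixtures.fixture_bezier("canon40d_red")
        assert not curve.x_monotone
        with pytest.raises(LUTError):
            build_lut(curve)


class TestLutLookup:
    def test_stored_node_exact(self, known_curve):
        lut = build_lut(known_curve)
        i = 100
        assert lut_lookup(lut, lut.response[i]) == lut.exposure[i]

    def test_midpoint_interpolation(self, known_curve):
        lut = build_lut(known_curve)
        mid_p = (lut.response[10] + lut.response[11]) / 2
        expected = (lut.exposure[10] + lut.exposure[11]) / 2
        assert lut_lookup(lut, mid_p) == pytest.approx(expected, rel=1e-12)

    def test_below_range_raises(self, known_curve):
        lut = build_lut(known_curve)
        with pytest.raises(BelowRangeError):
            lut_lookup(lut, known_curve.control_y[0] - 0.05)

    def test_above_range_saturates_with_warning(self, known_curve):
        lut = build_lut(known_curve)
        with pytest.warns(UserWarning):
            out = lut_lookup(lut, known_curve.control_y[3] + 0.01)
        assert out == lut.exposure[-1]

    def test_against_root_finding_oracle(self, known_curve):
        from scipy.optimize import brentq

        lut = build_lut(known_curve, 256)
        for p in np.linspace(0.2, 0.9, 29):
            # oracle: solve y(t) = p, then report x(t)
            t_star = brentq(
                lambda t: eval_bezier(known_curve, t)[1] - p, 0.0, 1.0
            )
            x_star = eval_bezier(known_curve, t_star)[0]
            assert abs(lut_lookup(lut, p) - x_star) <= 1.0 / (2 * 256)

    def test_round_trip_identity_on_samples(self, known_curve):
        lut = build_lut(known_curve, 256)
        ts = np.linspace(0, 1, 97)
        x, y = eval_bezier(known_curve, ts)
        looked = lut_lookup(lut, y)
        assert np.max(np.abs(looked - x)) <= 1.0 / (2 * 256)

    def test_denser_lut_reduces_round_trip_error(self, known_curve):
        ts = np.linspace(0, 1, 513)
        x, y = eval_bezier(known_curve, ts)
        err = {}
        for n in (256, 4096):
            lut = build_lut(known_curve, n)
            err[n] = np.max(np.abs(lut_lookup(lut, y) - x))
        assert err[4096] < err[256]


class TestSerialisation:
    def test_curve_json_round_trip(self, tmp_path):
        curve = fixtures.fixture_bezier("canon40d_blue")
        path = tmp_path / "curve.json"
        save_bezier_curve(curve, path)
        back = load_bezier_curve(path)
        np.testing.assert_allclose(back.control_x, curve.control_x)
        np.testing.assert_allclose(back.ci_y, curve.ci_y)
        assert back.p_min == curve.p_min

    def test_lut_csv_round_trip(self, tmp_path, known_curve):
        lut = build_lut(known_curve)
        path = tmp_path / "lut.csv"
        save_lut(lut, path)
        back = load_lut(path)
        np.testing.assert_allclose(back.response, lut.response)
        np.testing.assert_allclose(back.exposure, lut.exposure)

    def test_lut_requires_increasing_response(self):
        with pytest.raises(LUTError):
            LUT(response=np.array([0.2, 0.1]), exposure=np.array([0.1, 0.2]))
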