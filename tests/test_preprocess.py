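"""Torso averaging, proximity-axis projection, differentiation and filtering."""

import numpy as np
import pytest

from dyadsync import preprocess as pp
from dyadsync import io as mio
from dyadsync import xcorr
from dyadsync.errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    ParameterError,
)

from conftest import make_recording


def _rec_from_markers(child_markers, storyteller_markers, fps=120.0):
    n = next(iter(child_markers.values())).shape[0]
    return mio.LabeledRecording(
        {"child": child_markers, "storyteller": storyteller_markers},
        frames=np.arange(n),
        fps=fps,
    )


class TestAverageTorso:
    def test_single_marker_is_identity(self, rng):
        path = rng.normal(0, 10, (30, 3))
        rec = make_recording(path, np.zeros((30, 3)))
        np.testing.assert_array_equal(pp.average_torso(rec, "child").positions, path)

    def test_two_markers_midpoint(self):
        n = 5
        m1 = np.zeros((n, 3))
        m2 = np.tile([2.0, 0.0, 0.0], (n, 1))
        rec = _rec_from_markers({"a": m1, "b": m2}, {"s": np.ones((n, 3))})
        np.testing.assert_allclose(
            pp.average_torso(rec, "child").positions, np.tile([1.0, 0, 0], (n, 1))
        )

    def test_matches_brute_force_mean(self, rng):
        marks = {f"m{k}": rng.normal(0, 1, (50, 3)).cumsum(axis=0) for k in range(4)}
        rec = _rec_from_markers(marks, {"s": np.ones((50, 3))})
        centroid = pp.average_torso(rec, "child").positions
        expected = np.array(
            [np.mean([marks[m][t] for m in marks], axis=0) for t in range(50)]
        )
        np.testing.assert_allclose(centroid, expected, atol=1e-12)


class TestProximityAxis:
    def test_axis_aligned_geometry(self):
        a = pp.TorsoTrajectory(np.zeros((10, 3)), 120.0, "child")
        b = pp.TorsoTrajectory(np.tile([1000.0, 0, 0], (10, 1)), 120.0, "storyteller")
        axis = pp.estimate_axis(a, b)
        np.testing.assert_allclose(axis.unit_vector, [1.0, 0, 0])
        assert axis.sign("child") == +1 and axis.sign("storyteller") == -1

    def test_swapping_interactants_preserves_oriented_projection(self, rng):
        pa = rng.normal(0, 20, (40, 3)) + [0, 0, 1000]
        pb = rng.normal(0, 20, (40, 3)) + [900, 50, 1050]
        ta = pp.TorsoTrajectory(pa, 120.0, "child")
        tb = pp.TorsoTrajectory(pb, 120.0, "storyteller")
        ax1, ax2 = pp.estimate_axis(ta, tb), pp.estimate_axis(tb, ta)
        np.testing.assert_allclose(ax1.unit_vector, -ax2.unit_vector, atol=1e-12)
        np.testing.assert_allclose(
            pp.project(ta, ax1, "child"), pp.project(ta, ax2, "child"), atol=1e-9
        )

    def test_coincident_centroids_rejected(self):
        a = pp.TorsoTrajectory(np.zeros((5, 3)), 120.0, "child")
        b = pp.TorsoTrajectory(np.full((5, 3), 1e-4), 120.0, "storyteller")
        with pytest.raises(DegenerateGeometryError):
            pp.estimate_axis(a, b)


class TestProject:
    def _axis(self):
        return pp.ProximityAxis(np.array([1.0, 0, 0]), role_a="child", role_b="storyteller")

    def test_orthogonal_motion_projects_constant(self):
        path = np.zeros((20, 3))
        path[:, 1] = np.sin(np.arange(20))  # purely lateral
        out = pp.project(pp.TorsoTrajectory(path, 120.0, "child"), self._axis(), "child")
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_collinear_approach_increases_projection(self):
        path = np.zeros((10, 3))
        path[:, 0] = 10.0 * np.arange(10)  # child moving toward storyteller (+x)
        out = pp.project(pp.TorsoTrajectory(path, 120.0, "child"), self._axis(), "child")
        np.testing.assert_allclose(np.diff(out), 10.0)

    def test_matches_signed_dot_products(self, rng):
        path = rng.normal(0, 5, (30, 3))
        u = rng.normal(0, 1, 3)
        u /= np.linalg.norm(u)
        axis = pp.ProximityAxis(u, role_a="child", role_b="storyteller")
        expected = -np.array([np.dot(p, u) for p in path])  # storyteller sign is -1
        np.testing.assert_allclose(
            pp.project(pp.TorsoTrajectory(path, 120.0), axis, "storyteller"),
            expected,
            atol=1e-12,
        )

    def test_speed_invariant_to_rigid_translation_and_axis_rotation(self, rng):
        # translate the whole scene: projections shift by a constant, speeds don't move
        pa = rng.normal(0, 20, (40, 3))
        pb = rng.normal(0, 20, (40, 3)) + [1000, 0, 0]
        shift = np.array([123.0, -45.0, 67.0])
        ta, tb = pp.TorsoTrajectory(pa, 120, "child"), pp.TorsoTrajectory(pb, 120, "storyteller")
        ta2 = pp.TorsoTrajectory(pa + shift, 120, "child")
        tb2 = pp.TorsoTrajectory(pb + shift, 120, "storyteller")
        p1 = pp.project(ta, pp.estimate_axis(ta, tb), "child")
        p2 = pp.project(ta2, pp.estimate_axis(ta2, tb2), "child")
        np.testing.assert_allclose(np.diff(p1), np.diff(p2), atol=1e-9)
        # rotate the scene about the proximity axis: projections unchanged entirely
        axis = pp.estimate_axis(ta, tb)
        u = axis.unit_vector
        theta = 0.83
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        Rm = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        ta3 = pp.TorsoTrajectory(pa @ Rm.T, 120, "child")
        tb3 = pp.TorsoTrajectory(pb @ Rm.T, 120, "storyteller")
        p3 = pp.project(ta3, pp.estimate_axis(ta3, tb3), "child")
        np.testing.assert_allclose(p1, p3, atol=1e-9)


class TestDifferentiate:
    def test_constant_position_zero_speed(self):
        s = pp.differentiate(np.full(10, 7.0), fps=120.0)
        np.testing.assert_array_equal(s.values, np.zeros(9))

    def test_hand_difference(self):
        s = pp.differentiate(np.array([0.0, 3.0, 3.0, 1.0]), fps=120.0)
        np.testing.assert_array_equal(s.values, [3.0, 0.0, -2.0])

    def test_inverts_cumulative_sum(self, rng):
        v = rng.normal(0, 1, 500)
        pos = np.concatenate([[0.0], np.cumsum(v)])
        np.testing.assert_allclose(pp.differentiate(pos, 120.0).values, v, atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            pp.differentiate(np.array([1.0]), fps=120.0)


class TestLowpass:
    def test_unity_dc_gain(self):
        c = 5.0
        out = pp.lowpass(pp.SpeedSignal(np.full(500, c), 120.0))
        np.testing.assert_allclose(out.values, c, atol=1e-9)

    def test_smoothing_coefficient_value(self):
        # independent arithmetic: dt/(RC+dt), RC = 1/(2*pi*10), dt = 1/120
        dt = 1.0 / 120.0
        rc = 1.0 / (2.0 * np.pi * 10.0)
        assert pp.smoothing_coefficient(120.0, 10.0) == pytest.approx(dt / (rc + dt), abs=1e-12)
        assert pp.smoothing_coefficient(120.0, 10.0) == pytest.approx(0.3437, abs=5e-5)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            pp.smoothing_coefficient(120.0, 60.0)

    def test_zero_signal_stays_zero(self):
        out = pp.lowpass(pp.SpeedSignal(np.zeros(100), 120.0))
        np.testing.assert_array_equal(out.values, np.zeros(100))

    def test_attenuation_matches_transfer_function(self):
        # FFT amplitude-ratio oracle against |H(f)| = alpha / |1 - (1-alpha) e^{-i w}|
        fps, n = 120.0, 12000
        alpha = pp.smoothing_coefficient(fps, 10.0)
        t = np.arange(n) / fps
        for f in (2.0, 40.0):
            x = np.sin(2 * np.pi * f * t)
            y = pp.lowpass(pp.SpeedSignal(x, fps), 10.0).values
            steady = slice(n // 2, None)  # skip the startup transient
            ratio = np.sqrt(np.mean(y[steady] ** 2) / np.mean(x[steady] ** 2))
            w = 2 * np.pi * f / fps
            h = alpha / abs(1 - (1 - alpha) * np.exp(-1j * w))
            assert ratio == pytest.approx(h, rel=1e-3)
        # and a tone far above cutoff is attenuated more than one far below
        assert pp.lowpass(pp.SpeedSignal(np.sin(2 * np.pi * 40 * t), fps)).values.std() < \
            pp.lowpass(pp.SpeedSignal(np.sin(2 * np.pi * 2 * t), fps)).values.std()


class TestSignContract:
    """Approach-positive orientation: simultaneous mutual approach must come
    out positively correlated downstream, approach-vs-retreat negatively."""

    def _dyad(self, mirror: bool):
        n = 1200
        t = np.arange(n) / 120.0
        osc = 20.0 * np.sin(2 * np.pi * 1.0 * t)
        child = np.zeros((n, 3))
        story = np.zeros((n, 3))
        child[:, 0] = osc  # child at x~0 moving toward +x is approaching
        story[:, 0] = 1000.0 + (-osc if mirror else osc)
        return make_recording(child, story)

    @pytest.mark.parametrize("mirror,sign", [(True, 1), (False, -1)])
    def test_zero_lag_sign(self, mirror, sign):
        signals = pp.speed_signals(self._dyad(mirror))
        r = xcorr.corr(signals["storyteller"].values, signals["child"].values)
        assert np.sign(r) == sign and abs(r) > 0.99
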