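"""Angle conventions, angular velocity, laterality and mirroring."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tailbalance import errors, kinematics as kin

finite_pt = st.tuples(st.floats(-100, 100), st.floats(-100, 100))


class TestAngleAnchors:
    """The stated anchor values of the six angle conventions."""

    @pytest.mark.parametrize("seg,expected", [
        ((0.0, 10.0), 180.0),    # tail pointing straight up
        ((0.0, -10.0), 0.0),     # straight down
        ((10.0, -10.0), 45.0),   # halfway down on the left
        ((10.0, 0.0), 90.0),     # horizontal
        ((-10.0, -10.0), 315.0),  # mirrored quadrant
    ])
    def test_roll_tail(self, seg, expected):
        assert kin.roll_tail_angle((0.0, 0.0), seg) == pytest.approx(expected)

    @pytest.mark.parametrize("seg,expected", [
        ((-10.0, 0.0), 0.0),                 # straight back
        ((0.0, 10.0), -90.0),                # perpendicular
        ((-10.0, -10.0), 45.0),              # back + lateral, 45 magnitude
    ])
    def test_yaw_tail(self, seg, expected):
        ang = kin.yaw_tail_angle((0.0, 0.0), seg)
        assert ang == pytest.approx(expected)
        # oracle: atan2 of cross/dot against the backward axis
        bx, by = -1.0, 0.0
        oracle = math.degrees(math.atan2(bx * seg[1] - by * seg[0],
                                         bx * seg[0] + by * seg[1]))
        assert ang == pytest.approx(oracle)

    @pytest.mark.parametrize("lh,rh,expected", [
        ((0.0, 5.0), (10.0, 5.0), 90.0),   # horizontal alignment
        ((0.0, 0.0), (0.0, 8.0), 0.0),     # vertical line
        ((0.0, 0.0), (10.0, 10.0), 45.0),  # atan2 oracle value
        ((0.0, 10.0), (10.0, 0.0), 135.0),  # opposite inclination
    ])
    def test_hip(self, lh, rh, expected):
        assert kin.hip_angle(lh, rh) == pytest.approx(expected)

    def test_back_angle_anchors(self):
        base = (0.0, 0.0)
        assert kin.back_angle(base, (10.0, 0.0)) == pytest.approx(0.0)
        assert abs(kin.back_angle(base, (10.0, 10.0))) == pytest.approx(45.0)
        # reflection antisymmetry
        assert kin.back_angle(base, (10.0, -10.0)) == pytest.approx(
            -kin.back_angle(base, (10.0, 10.0)))

    def test_front_angle_anchors(self):
        assert kin.front_angle((0.0, 0.0), (10.0, 0.0)) == pytest.approx(0.0)
        assert abs(kin.front_angle((0.0, 0.0), (0.0, 10.0))) == pytest.approx(90.0)
        # arbitrary configuration against the atan2 oracle
        cen, nose = (3.0, -2.0), (7.5, 1.0)
        v = (nose[0] - cen[0], nose[1] - cen[1])
        oracle = math.degrees(math.atan2(v[1], v[0]))
        assert kin.front_angle(cen, nose) == pytest.approx(oracle)

    def test_coincident_points_rejected(self):
        with pytest.raises(errors.UndefinedAngleError):
            kin.roll_tail_angle((1.0, 1.0), (1.0, 1.0))
        with pytest.raises(errors.UndefinedAngleError):
            kin.hip_angle((2.0, 3.0), (2.0, 3.0))


class TestTailOnBody:
    def _trace(self, name, vals):
        return kin.AngleTrace(name, np.asarray(vals, float), "test", 300.0)

    @pytest.mark.parametrize("tail,back,expected", [
        (30.0, 30.0, 0.0),
        (90.0, 10.0, 80.0),
        (-170.0, 20.0, 170.0),  # wraps through the branch cut
    ])
    def test_subtraction_with_wrap(self, tail, back, expected):
        out = kin.tail_on_body_angle(self._trace("back", [back]),
                                     self._trace("yaw_tail", [tail]))
        assert out.values[0] == pytest.approx(expected)

    def test_self_cancellation(self):
        tr = self._trace("back", np.linspace(-170, 170, 50))
        out = kin.tail_on_body_angle(tr, tr)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(errors.ShapeError):
            kin.tail_on_body_angle(self._trace("back", [0, 1]),
                                   self._trace("yaw_tail", [0]))


class TestInvariances:
    @given(base=finite_pt, seg=finite_pt,
           dx=st.floats(-50, 50), dy=st.floats(-50, 50),
           scale=st.floats(0.1, 10))
    def test_translation_and_scaling(self, base, seg, dx, dy, scale):
        v = (seg[0] - base[0], seg[1] - base[1])
        if abs(v[0]) < 1e-6 and abs(v[1]) < 1e-6:
            return
        ref = kin.roll_tail_angle(base, seg)
        moved = kin.roll_tail_angle(
            (base[0] + dx, base[1] + dy),
            (base[0] + dx + scale * v[0], base[1] + dy + scale * v[1]))
        assert moved == pytest.approx(ref, abs=1e-9)

    def test_roll_mirror_reflects_about_vertical(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(50, 2))
        seg = base + rng.normal(size=(50, 2)) + 0.5
        theta = kin.roll_tail_angle(base, seg)
        mirrored = kin.roll_tail_angle(base * [-1, 1], seg * [-1, 1])
        np.testing.assert_allclose(mirrored, np.mod(360 - theta, 360),
                                   atol=1e-9)

    def test_double_mirror_is_identity(self):
        rng = np.random.default_rng(1)
        angles = {
            "roll_tail": kin.AngleTrace("roll_tail",
                                        rng.uniform(0, 360, 40), "c"),
            "yaw_tail": kin.AngleTrace("yaw_tail",
                                       rng.uniform(-179, 180, 40), "c"),
            "hip": kin.AngleTrace("hip", rng.uniform(0, 180, 40), "c"),
            "back": kin.AngleTrace("back", rng.uniform(-90, 90, 40), "c"),
            "front": kin.AngleTrace("front", rng.uniform(-90, 90, 40), "c"),
            "tail_on_body": kin.AngleTrace("tail_on_body",
                                           rng.uniform(-179, 180, 40), "c"),
        }
        once = kin.mirror_normalize(angles, "left")
        twice = kin.mirror_normalize(once, "left")
        for name in angles:
            np.testing.assert_allclose(
                np.mod(twice[name].values, 360.0),
                np.mod(angles[name].values, 360.0), atol=1e-9)


class TestAngularVelocity:
    def test_linear_ramp(self):
        trace = kin.AngleTrace("roll_tail", np.linspace(0, 90, 301), "c", 300.0)
        np.testing.assert_allclose(kin.angular_velocity(trace), 90.0,
                                   rtol=1e-9)

    def test_constant_angle_zero(self):
        trace = kin.AngleTrace("hip", np.full(100, 42.0), "c", 300.0)
        np.testing.assert_allclose(kin.angular_velocity(trace), 0.0)

    def test_sinusoid_peak_matches_analytic(self):
        f, A, fr = 3.0, 30.0, 300.0
        t = np.arange(int(2 * fr)) / fr
        trace = kin.AngleTrace("roll_tail", A * np.sin(2 * np.pi * f * t),
                               "c", fr)
        peak = np.abs(kin.angular_velocity(trace)).max()
        assert peak == pytest.approx(2 * np.pi * f * A, rel=0.005)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(-30, 30, 200)
        a = kin.AngleTrace("back", vals, "c", 300.0)
        b = kin.AngleTrace("back", vals + 57.0, "c", 300.0)
        np.testing.assert_allclose(kin.angular_velocity(a),
                                   kin.angular_velocity(b), atol=1e-9)

    def test_unwrap_across_the_wrap_point(self):
        # steady rotation crossing 360 must not produce velocity spikes
        fr = 300.0
        vals = np.mod(np.linspace(300, 420, 121), 360.0)
        trace = kin.AngleTrace("roll_tail", vals, "c", fr)
        np.testing.assert_allclose(kin.angular_velocity(trace), 300.0,
                                   rtol=1e-9)


class TestLaterality:
    def test_il_when_tilt_matches_tail_side(self):
        lat = kin.classify_laterality(75.0, "left")
        assert (lat.tail_side, lat.label) == ("left", "IL")

    def test_cl_when_opposite(self):
        assert kin.classify_laterality(75.0, "right").label == "CL"

    def test_label_invariant_under_simultaneous_mirror(self):
        lat = kin.classify_laterality(75.0, "left")
        mirrored = kin.classify_laterality(float(kin.mirror_roll(75.0)),
                                           "right")
        assert mirrored.label == lat.label
        assert mirrored.tail_side == "right"

    def test_vertical_tail_unclassifiable(self):
        with pytest.raises(errors.UndefinedAngleError):
            kin.classify_laterality(180.0, "left")
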