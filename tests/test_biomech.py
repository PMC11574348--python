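"""Rod/cylinder angular-momentum model and window integration."""

import numpy as np
import pytest

from tailbalance import biomech, errors
from tailbalance.biomech import BodyModel, MomentumTrace, TiltProfile


def rod_inertia_numeric(mass, length, n=200_000):
    """Oracle: midpoint discretization of a uniform rod about its end."""
    dx = length / n
    x = (np.arange(n) + 0.5) * dx
    return float(np.sum(mass / n * x ** 2))


def cylinder_inertia_numeric(mass, radius, n_r=3000, n_th=64):
    """Oracle: 2-D polar quadrature of a uniform disc about its axis."""
    dr = radius / n_r
    r = (np.arange(n_r) + 0.5) * dr
    dth = 2 * np.pi / n_th
    rho = mass / (np.pi * radius ** 2)
    ring = rho * r ** 3 * dr * dth  # per angular sector
    return float(np.sum(np.tile(ring, (n_th, 1))))


class TestInertias:
    def test_rod_closed_form_matches_mass_integration(self):
        model = BodyModel()
        oracle = rod_inertia_numeric(model.tail_mass, model.tail_length)
        assert abs(model.tail_inertia - oracle) / oracle < 1e-6

    def test_cylinder_closed_form_matches_quadrature(self):
        model = BodyModel()
        oracle = cylinder_inertia_numeric(model.body_mass, model.body_radius)
        assert abs(model.body_inertia - oracle) / oracle < 1e-6

    def test_center_axis_rod_is_one_quarter_of_end_axis(self):
        end = BodyModel(tail_axis="end").tail_inertia
        center = BodyModel(tail_axis="center").tail_inertia
        assert center == pytest.approx(end / 4.0)


class TestMomentumTraces:
    def test_tail_momentum_at_reported_swing_speed(self):
        # 2.2 rotations/s with the rod constants: L = (1/3) m l^2 omega
        model = BodyModel()
        omega = 2.2 * 2 * np.pi  # 13.823 rad/s
        trace = biomech.tail_momentum(np.array([omega]), model)
        expected = (1.0 / 3.0) * 0.0005 * 0.07 ** 2 * omega
        assert trace.values[0] == pytest.approx(expected, rel=1e-12)
        assert trace.values[0] == pytest.approx(1.129e-5, rel=1e-3)

    def test_zero_omega_gives_zero(self):
        trace = biomech.tail_momentum(np.zeros(5), BodyModel())
        np.testing.assert_array_equal(trace.values, 0.0)

    def test_doubling_length_quadruples_tail_momentum(self):
        w = np.array([1.0])
        L1 = biomech.tail_momentum(w, BodyModel(tail_length=0.07)).values[0]
        L2 = biomech.tail_momentum(w, BodyModel(tail_length=0.14)).values[0]
        assert L2 == pytest.approx(4 * L1)

    def test_body_momentum_unit_omega(self):
        trace = biomech.body_momentum(np.array([1.0]), BodyModel())
        assert trace.values[0] == pytest.approx(0.5 * 0.02 * 0.01 ** 2)
        assert trace.values[0] == pytest.approx(1.0e-6)

    def test_body_momentum_linear_in_mass(self):
        w = np.array([2.0])
        L1 = biomech.body_momentum(w, BodyModel(body_mass=0.02)).values[0]
        L2 = biomech.body_momentum(w, BodyModel(body_mass=0.04)).values[0]
        assert L2 == pytest.approx(2 * L1)

    def test_non_finite_omega_rejected(self):
        with pytest.raises(errors.ParameterError):
            biomech.tail_momentum(np.array([1.0, np.nan]), BodyModel())

    def test_sum_equals_tail_plus_body_exactly(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=100)
        model = BodyModel()
        tail = biomech.tail_momentum(w, model)
        body = biomech.body_momentum(2 * w, model)
        total = biomech.sum_momentum(tail, body)
        np.testing.assert_array_equal(total.values,
                                      tail.values + body.values)


class TestPerturbation:
    def test_cylinder_variant_with_baseline_tilt(self):
        # 20 deg over 190 ms: omega_p = 1.8372 rad/s
        model = BodyModel()
        tilt = TiltProfile(20.0, 0.19, "left", onset=0)
        assert tilt.peak_omega == pytest.approx(1.8372, rel=1e-4)
        trace = biomech.perturbation_momentum(
            tilt, model, n_frames=10, frame_rate=300.0,
            variant="cylinder_platform_radius")
        expected = 0.5 * 0.0205 * model.platform_radius ** 2 * tilt.peak_omega
        assert trace.values[0] == pytest.approx(expected, rel=1e-12)
        # with r = 1 cm the printed reference value applies
        model_cm = BodyModel(platform_radius=0.01)
        trace_cm = biomech.perturbation_momentum(
            tilt, model_cm, 10, 300.0, "cylinder_platform_radius")
        assert trace_cm.values[0] == pytest.approx(1.883e-6, rel=1e-3)

    def test_momentum_zero_after_ramp(self):
        tilt = TiltProfile(20.0, 0.19, "left", onset=30)
        trace = biomech.perturbation_momentum(tilt, BodyModel(), 300, 300.0)
        assert trace.values[29] == 0.0
        assert trace.values[30] != 0.0
        assert trace.values[30 + 57] == 0.0  # 0.19 s at 300 fps = 57 frames

    def test_zero_amplitude_zero_trace(self):
        tilt = TiltProfile(1e-12, 0.19, "left", onset=0)
        trace = biomech.perturbation_momentum(tilt, BodyModel(), 100, 300.0)
        np.testing.assert_allclose(trace.values, 0.0, atol=1e-15)

    def test_variant_inertias(self):
        m = BodyModel()
        M = m.total_mass
        assert m.perturbation_inertia("cylinder_platform_radius") == \
            pytest.approx(0.5 * M * m.platform_radius ** 2)
        assert m.perturbation_inertia("point_mass_at_edge") == \
            pytest.approx(M * m.body_radius ** 2)
        assert m.perturbation_inertia("cylinder_plus_parallel_axis") == \
            pytest.approx(0.5 * M * m.body_radius ** 2 + M * m.body_radius ** 2)
        with pytest.raises(errors.ConfigError):
            m.perturbation_inertia("nonsense")


class TestIntegration:
    def test_constant_rectangle(self):
        trace = MomentumTrace("tail", np.full(151, 2.0), 300.0)
        assert biomech.integrate_momentum(trace, (0.0, 0.5)) == \
            pytest.approx(1.0, rel=1e-9)

    def test_antisymmetric_swing_cancels_signed_not_absolute(self):
        t = np.arange(301) / 300.0
        trace = MomentumTrace("tail", np.sin(2 * np.pi * t), 300.0)
        signed = biomech.integrate_momentum(trace, (0.0, 1.0), "signed")
        absolute = biomech.integrate_momentum(trace, (0.0, 1.0), "absolute")
        assert abs(signed) < 1e-6
        assert absolute > 0.5

    def test_trapezoid_converges_quadratically(self):
        # analytic: integral of sin over a half period = 2/omega
        errs = []
        for fr in (100.0, 200.0, 400.0):
            t = np.arange(int(fr) + 1) / fr
            trace = MomentumTrace("tail", np.sin(np.pi * t), fr)
            val = biomech.integrate_momentum(trace, (0.0, 1.0))
            errs.append(abs(val - 2 / np.pi))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.1)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.1)

    def test_totals_additive_over_adjacent_windows(self):
        rng = np.random.default_rng(1)
        trace = MomentumTrace("body", rng.normal(size=601), 300.0)
        whole = biomech.integrate_momentum(trace, (0.1, 1.9))
        split = (biomech.integrate_momentum(trace, (0.1, 0.77))
                 + biomech.integrate_momentum(trace, (0.77, 1.9)))
        assert split == pytest.approx(whole, abs=1e-12)

    def test_empty_window_rejected(self):
        trace = MomentumTrace("tail", np.ones(100), 300.0)
        with pytest.raises(errors.ParameterError):
            biomech.integrate_momentum(trace, (0.2, 0.2))


class TestPhasesAndRatios:
    def test_constant_trace_early_late_split(self):
        trace = MomentumTrace("tail", np.ones(301), 300.0)
        tilt = TiltProfile(20.0, 0.19, "left", onset=0)
        phases = biomech.split_phases(trace, tilt, response_window=0.5)
        assert phases["early"] == pytest.approx(0.19, rel=1e-6)
        assert phases["late"] == pytest.approx(0.31, rel=1e-6)

    def test_zero_trace_zero_phases(self):
        trace = MomentumTrace("tail", np.zeros(301), 300.0)
        tilt = TiltProfile(20.0, 0.19, "left", onset=0)
        phases = biomech.split_phases(trace, tilt)
        assert phases == {"early": 0.0, "late": 0.0}

    def test_impulse_inside_ramp_has_no_late_component(self):
        vals = np.zeros(301)
        vals[10:20] = 1.0  # support entirely within the 57-frame ramp
        trace = MomentumTrace("tail", vals, 300.0)
        tilt = TiltProfile(20.0, 0.19, "left", onset=0)
        phases = biomech.split_phases(trace, tilt)
        assert phases["late"] == 0.0
        assert phases["early"] > 0.0

    @pytest.mark.parametrize("tail,body,expected_sum", [
        (1.0, 0.0, 1.0),
        (0.0, 0.0, 0.0),
        (0.5, 0.3, 0.8),
    ])
    def test_relative_momentum(self, tail, body, expected_sum):
        rel = biomech.relative_momentum(tail, body, 1.0)
        assert rel["sum"] == pytest.approx(expected_sum)

    def test_relative_momentum_absent_without_perturbation(self):
        assert biomech.relative_momentum(1.0, 1.0, 0.0) is None
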