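"""Rod/cylinder angular-momentum model for tail, body and perturbation.

The tail is a uniform rod (length l, mass m_t) rotating in the roll plane;
because the swing starts from the tail base the default moment of inertia
is the end-axis value I = (1/3) m_t l^2 (a centre-axis switch is provided).
The body is a solid cylinder about its long axis, I = (1/2) m_b r_b^2.
The perturbation is the momentum imparted to the whole animal by the
tilting platform; its moment of inertia is ambiguous at this level of
modelling, so three variants are implemented:

* ``cylinder_platform_radius``: I = (1/2) M r_p^2 — whole animal as a
  cylinder of the platform's radius;
* ``point_mass_at_edge``: I = M d^2 — animal as a point mass a distance d
  from the rotation axis;
* ``cylinder_plus_parallel_axis`` (default): I = (1/2) M r_b^2 + M d^2 with
  d = r_b — body cylinder displaced one body radius from the axis.

with M = m_b + m_t.  Angular momentum is L(t) = I * omega(t)
(kg m^2 s^-1); totals are trapezoidal time integrals, signed by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ParameterError, ShapeError

PERTURBATION_VARIANTS = ("cylinder_platform_radius", "point_mass_at_edge",
                         "cylinder_plus_parallel_axis")


@dataclass
class BodyModel:
    """Anatomical constants (SI units), from adult C57BL/6 carcass averages:
    7 cm / 0.5 g tail, 2 cm diameter / 20 g body."""

    tail_mass: float = 0.0005    # kg
    tail_length: float = 0.07    # m
    body_mass: float = 0.020     # kg
    body_radius: float = 0.01    # m
    platform_radius: float = 0.005  # m, ridge half-width (config)
    tail_axis: str = "end"       # 'end' (I = m l^2 / 3) or 'center' (/12)

    def __post_init__(self) -> None:
        for name in ("tail_mass", "tail_length", "body_mass",
                     "body_radius", "platform_radius"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.tail_axis not in ("end", "center"):
            raise ConfigError("tail_axis must be 'end' or 'center'")

    @property
    def tail_inertia(self) -> float:
        factor = 1.0 / 3.0 if self.tail_axis == "end" else 1.0 / 12.0
        return factor * self.tail_mass * self.tail_length ** 2

    @property
    def body_inertia(self) -> float:
        return 0.5 * self.body_mass * self.body_radius ** 2

    @property
    def total_mass(self) -> float:
        return self.body_mass + self.tail_mass

    def perturbation_inertia(self, variant: str = "cylinder_plus_parallel_axis",
                             d: float | None = None) -> float:
        M = self.total_mass
        if d is None:
            d = self.body_radius
        if variant == "cylinder_platform_radius":
            return 0.5 * M * self.platform_radius ** 2
        if variant == "point_mass_at_edge":
            return M * d ** 2
        if variant == "cylinder_plus_parallel_axis":
            return 0.5 * M * self.body_radius ** 2 + M * d ** 2
        raise ConfigError(f"unknown perturbation variant {variant!r}")


@dataclass
class TiltProfile:
    """Constant-rate ramp tilt of the ridge: ``amplitude`` degrees over
    ``duration`` seconds starting at frame ``onset``; the ridge then stays
    tilted, so the platform angular velocity is amplitude/duration during
    the ramp and zero elsewhere.  Left tilts are positive rotations."""

    amplitude: float              # deg
    duration: float               # s
    direction: str                # 'left' | 'right'
    onset: int                    # frame index

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("tilt duration must be positive")
        if self.direction not in ("left", "right"):
            raise ConfigError("tilt direction must be 'left' or 'right'")

    @property
    def peak_omega(self) -> float:
        """Platform angular speed during the ramp, rad/s (unsigned)."""
        return np.radians(self.amplitude) / self.duration

    def omega_series(self, n_frames: int, frame_rate: float) -> np.ndarray:
        """Signed platform angular velocity per frame, rad/s."""
        omega = np.zeros(n_frames)
        stop = self.onset + int(round(self.duration * frame_rate))
        sign = 1.0 if self.direction == "left" else -1.0
        omega[max(self.onset, 0):min(stop, n_frames)] = sign * self.peak_omega
        return omega


@dataclass
class MomentumTrace:
    """Instantaneous angular momentum (kg m^2 s^-1) from one source."""

    source: str                   # 'tail' | 'body' | 'perturbation' | 'sum'
    values: np.ndarray
    frame_rate: float = 300.0
    window_totals: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate


def _check_finite(omega: np.ndarray) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ParameterError("angular velocity contains non-finite samples")
    return omega


def tail_momentum(omega_tail: np.ndarray, model: BodyModel,
                  frame_rate: float = 300.0) -> MomentumTrace:
    """L(t) = I_tail * omega(t) for the tail rod (omega in rad/s)."""
    omega = _check_finite(omega_tail)
    return MomentumTrace("tail", model.tail_inertia * omega, frame_rate,
                         meta={"inertia": model.tail_inertia,
                               "tail_axis": model.tail_axis})


def body_momentum(omega_body: np.ndarray, model: BodyModel,
                  frame_rate: float = 300.0) -> MomentumTrace:
    """L(t) = I_body * omega(t) for the body cylinder (omega in rad/s)."""
    omega = _check_finite(omega_body)
    return MomentumTrace("body", model.body_inertia * omega, frame_rate,
                         meta={"inertia": model.body_inertia})


def perturbation_momentum(tilt: TiltProfile, model: BodyModel,
                          n_frames: int, frame_rate: float = 300.0,
                          variant: str = "cylinder_plus_parallel_axis",
                          ) -> MomentumTrace:
    """Momentum imparted by the tilting platform under the chosen inertia
    variant; zero outside the tilt ramp."""
    inertia = model.perturbation_inertia(variant)
    omega = tilt.omega_series(n_frames, frame_rate)
    return MomentumTrace("perturbation", inertia * omega, frame_rate,
                         meta={"inertia": inertia, "variant": variant})


def sum_momentum(tail: MomentumTrace, body: MomentumTrace) -> MomentumTrace:
    if len(tail.values) != len(body.values):
        raise ShapeError("tail and body momentum traces differ in length")
    return MomentumTrace("sum", tail.values + body.values, tail.frame_rate)


def integrate_momentum(trace: MomentumTrace, window: tuple[float, float],
                       mode: str = "signed") -> float:
    """Trapezoidal time integral of L (or |L|) over ``window`` seconds."""
    t0, t1 = window
    if not t1 > t0:
        raise ParameterError("integration window must satisfy t1 > t0")
    if mode not in ("signed", "absolute"):
        raise ConfigError(f"unknown integration mode {mode!r}")
    t = trace.times
    if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
        raise ParameterError("integration window outside the trace")
    # resample the trapezoid exactly at the window edges
    grid = t[(t > t0) & (t < t1)]
    tt = np.concatenate(([t0], grid, [t1]))
    vals = np.interp(tt, t, trace.values)
    if mode == "absolute":
        vals = np.abs(vals)
    return float(np.trapezoid(vals, tt))


def relative_momentum(tail_total: float, body_total: float,
                      pert_total: float) -> dict[str, float] | None:
    """Totals normalized by the perturbation total: tail/pert, body/pert and
    their sum.  Returns None when there is no perturbation momentum."""
    if pert_total == 0:
        return None
    return {"tail": tail_total / pert_total,
            "body": body_total / pert_total,
            "sum": (tail_total + body_total) / pert_total}


def split_phases(trace: MomentumTrace, tilt: TiltProfile,
                 response_window: float = 0.5,
                 mode: str = "signed") -> dict[str, float]:
    """Early/late totals around the tilt: early = integral over the tilt ramp,
    late = from ramp end to ``response_window`` seconds after onset."""
    onset_t = tilt.onset / trace.frame_rate
    t_end = trace.times[-1]
    early_stop = min(onset_t + tilt.duration, t_end)
    late_stop = min(onset_t + response_window, t_end)
    if late_stop < onset_t + response_window - 1e-12:
        import warnings
        warnings.warn("response window truncated at the end of the trace")
    early = integrate_momentum(trace, (onset_t, early_stop), mode)
    late = (integrate_momentum(trace, (early_stop, late_stop), mode)
            if late_stop > early_stop else 0.0)
    return {"early": early, "late": late}
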