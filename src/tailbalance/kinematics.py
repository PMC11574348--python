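"""Angle definitions, angular velocity and trial laterality.

All angles are computed in math coordinates (y up) on whichever camera view
the definition names.  Conventions:

* roll-plane tail angle (rear view): angle of the tail-base -> first tail
  marker vector measured from straight down, so 0 deg = tail hanging
  straight down, 90 deg = horizontal, 180 deg = tail pointing straight up;
  range [0, 360).  Angles in (0, 180) place the tail tip at positive rear
  x, which this package labels the animal's *left* side (the rear camera
  faces the animal from behind).
* yaw-plane tail angle (top view): signed angle between the backward ridge
  direction and the tail segment; 0 = tail straight back, range (-180, 180].
* hip angle (rear view): undirected hip-line angle from vertical in
  [0, 180]; 90 = horizontal.
* back / front angles (top view): signed deviation of the hind body / head
  axis from the ridge direction; 0 = aligned with the ridge.
* tail-on-body angle: yaw tail angle minus back angle, wrapped to
  (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError, ShapeError, UndefinedAngleError

ANGLE_NAMES = ("roll_tail", "yaw_tail", "hip", "back", "front", "tail_on_body")

#: Forward direction of the ridge in top-view math coordinates.
RIDGE_AXIS = np.array([1.0, 0.0])


@dataclass
class AngleTrace:
    """A named angle time series in degrees with an explicit convention."""

    name: str
    values: np.ndarray
    convention: str
    frame_rate: float = 300.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ParameterError(f"angle trace {self.name!r} has non-finite values")

    @property
    def n_frames(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Laterality:
    """Which side the tail is held on, and the IL/CL trial label."""

    tail_side: str  # 'left' | 'right'
    label: str      # 'IL' | 'CL'


def _as_points(p) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(p, dtype=float))
    if arr.shape[-1] != 2:
        raise ShapeError("points must have an (x, y) last axis")
    return arr


def _check_distinct(v: np.ndarray, what: str) -> None:
    if np.any(np.all(v == 0.0, axis=-1)):
        raise UndefinedAngleError(f"coincident points in {what}")


def _maybe_scalar(values: np.ndarray, *inputs) -> np.ndarray | float:
    scalar = all(np.asarray(p).ndim == 1 for p in inputs)
    return float(values[0]) if scalar and values.size == 1 else values


def wrap_degrees(angle) -> np.ndarray | float:
    """Wrap angles to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return float(wrapped) if np.isscalar(angle) else wrapped


def signed_angle(reference: np.ndarray, vector: np.ndarray) -> np.ndarray:
    """Signed angle (deg, (-180, 180]) from ``reference`` to ``vector``,
    positive counter-clockwise."""
    cross = reference[..., 0] * vector[..., 1] - reference[..., 1] * vector[..., 0]
    dot = (reference * vector).sum(axis=-1)
    ang = np.degrees(np.arctan2(cross, dot))
    return wrap_degrees(ang)


# ---------------------------------------------------------------------------
# the six angle definitions
# ---------------------------------------------------------------------------

def roll_tail_angle(tail_base, tail_seg):
    """Roll-plane tail angle (rear view): 0 = down, 90 = horizontal,
    180 = up; range [0, 360)."""
    base, seg = _as_points(tail_base), _as_points(tail_seg)
    v = seg - base
    _check_distinct(v, "roll tail angle")
    ang = np.degrees(np.arctan2(v[..., 0], -v[..., 1])) % 360.0
    return _maybe_scalar(ang, tail_base, tail_seg)


def yaw_tail_angle(tail_base, tail_seg, ridge_axis=RIDGE_AXIS):
    """Yaw-plane tail angle (top view): signed deviation from the backward
    ridge direction; 0 = tail straight back."""
    base, seg = _as_points(tail_base), _as_points(tail_seg)
    axis = np.asarray(ridge_axis, dtype=float)
    v = seg - base
    _check_distinct(v, "yaw tail angle")
    ang = signed_angle(-axis, v)
    return _maybe_scalar(ang, tail_base, tail_seg)


def hip_angle(left_hip, right_hip):
    """Hip-line angle from vertical (rear view), in [0, 180]; 90 = horizontal."""
    lh, rh = _as_points(left_hip), _as_points(right_hip)
    v = rh - lh
    _check_distinct(v, "hip angle")
    norm = np.linalg.norm(v, axis=-1)
    cosang = np.clip(v[..., 1] / norm, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return _maybe_scalar(ang, left_hip, right_hip)


def back_angle(tail_base, centroid, ridge_axis=RIDGE_AXIS):
    """Hind-body alignment (top view): signed angle at the tail base between
    the forward ridge direction and the base -> centroid vector; 0 = hind
    body aligned straight back along the ridge."""
    base, cen = _as_points(tail_base), _as_points(centroid)
    axis = np.asarray(ridge_axis, dtype=float)
    v = cen - base
    _check_distinct(v, "back angle")
    ang = signed_angle(axis, v)
    return _maybe_scalar(ang, tail_base, centroid)


def front_angle(centroid, nose, ridge_axis=RIDGE_AXIS):
    """Head alignment (top view): signed angle between the forward ridge
    direction and the centroid -> nose vector; 0 = head straight ahead."""
    cen, ns = _as_points(centroid), _as_points(nose)
    axis = np.asarray(ridge_axis, dtype=float)
    v = ns - cen
    _check_distinct(v, "front angle")
    ang = signed_angle(axis, v)
    return _maybe_scalar(ang, centroid, nose)


def tail_on_body_angle(back: AngleTrace, tail_yaw: AngleTrace) -> AngleTrace:
    """Yaw tail angle relative to the hind-body axis: frame-wise
    ``tail_yaw - back`` wrapped to (-180, 180]."""
    if back.n_frames != tail_yaw.n_frames:
        raise ShapeError("back and tail yaw traces differ in length")
    if back.frame_rate != tail_yaw.frame_rate:
        raise ShapeError("back and tail yaw traces differ in frame rate")
    vals = wrap_degrees(tail_yaw.values - back.values)
    return AngleTrace("tail_on_body", vals,
                      "tail yaw minus back angle, 0 = tail straight back",
                      back.frame_rate)


# ---------------------------------------------------------------------------
# velocity, laterality, mirroring
# ---------------------------------------------------------------------------

def angular_velocity(angle: AngleTrace) -> np.ndarray:
    """Instantaneous angular velocity (deg/s): central-difference gradient of
    the unwrapped angle scaled by the frame rate (one-sided at the ends)."""
    if angle.n_frames < 2:
        raise ShapeError("angular velocity needs at least 2 frames")
    unwrapped = np.unwrap(angle.values, period=360.0)
    return np.gradient(unwrapped) * angle.frame_rate


def classify_laterality(roll_tail_at_onset: float,
                        tilt_direction: str) -> Laterality:
    """IL/CL trial label from the roll-plane tail angle at tilt onset.

    Roll angles in (0, 180) put the tail on the animal's left; (180, 360)
    on the right.  A tail exactly vertical (0 or 180) has no side and the
    trial is flagged unclassifiable.
    """
    if tilt_direction not in ("left", "right"):
        raise ParameterError("tilt_direction must be 'left' or 'right'")
    theta = float(roll_tail_at_onset) % 360.0
    if theta in (0.0, 180.0):
        raise UndefinedAngleError(
            "tail exactly vertical at tilt onset: laterality unclassifiable")
    side = "left" if 0.0 < theta < 180.0 else "right"
    return Laterality(tail_side=side,
                      label="IL" if side == tilt_direction else "CL")


def mirror_roll(values):
    """Reflect a roll-plane angle about the vertical: theta -> 360 - theta
    (mod 360)."""
    return np.mod(360.0 - np.asarray(values, dtype=float), 360.0)


def mirror_normalize(angles: dict[str, AngleTrace],
                     tail_side: str) -> dict[str, AngleTrace]:
    """Mirror a left-tailed trial so the tail side is canonically 'right'.

    Reflects the roll-plane tail angle about the vertical and negates the
    signed top-view angles; right-tailed trials pass through unchanged.
    Applying the normalization twice with the flipped side is the identity.
    """
    if tail_side == "right":
        return dict(angles)
    out: dict[str, AngleTrace] = {}
    for name, tr in angles.items():
        if name == "roll_tail":
            out[name] = replace(tr, values=mirror_roll(tr.values))
        elif name == "hip":
            out[name] = replace(tr, values=tr.values.copy())
        else:
            out[name] = replace(tr, values=wrap_degrees(-tr.values))
    return out


def compute_angles(rear, top, centroid_xy: np.ndarray,
                   ridge_axis=RIDGE_AXIS) -> dict[str, AngleTrace]:
    """All six angle traces from conditioned two-view keypoint tables.

    ``rear`` must carry tail_base, tail_1, hip_left, hip_right; ``top``
    must carry nose and tail_base, tail_1; ``centroid_xy`` is the top-view
    centroid as an (n, 2) array on the same frame index.
    """
    fr = rear.frame_rate
    roll = AngleTrace(
        "roll_tail",
        roll_tail_angle(rear.point("tail_base"), rear.point("tail_1")),
        "0 deg = down, 180 deg = up, (0,180) = left side", fr)
    yaw = AngleTrace(
        "yaw_tail",
        yaw_tail_angle(top.point("tail_base"), top.point("tail_1"), ridge_axis),
        "0 deg = straight back, signed", fr)
    hip = AngleTrace(
        "hip",
        hip_angle(rear.point("hip_left"), rear.point("hip_right")),
        "angle from vertical, 90 deg = horizontal", fr)
    back = AngleTrace(
        "back",
        back_angle(top.point("tail_base"), centroid_xy, ridge_axis),
        "0 deg = hind body straight back along the ridge", fr)
    front = AngleTrace(
        "front",
        front_angle(centroid_xy, top.point("nose"), ridge_axis),
        "0 deg = head straight ahead along the ridge", fr)
    tob = tail_on_body_angle(back, yaw)
    return {"roll_tail": roll, "yaw_tail": yaw, "hip": hip,
            "back": back, "front": front, "tail_on_body": tob}
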