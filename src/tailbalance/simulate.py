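"""Synthetic two-view ridge-crossing trials with known ground truth.

The generator emulates the statistical structure the analysis assumes, not
the videos themselves: step-locked sinusoidal paw/hip/tail oscillations
(tail anti-phase to the hips by default), a side-held tail posture whose
mean and oscillation amplitude depend on ridge width (narrower ridges:
lower, larger-amplitude tails), forward centroid progress with smooth
lateral wander, and — on tilt trials — a stereotyped minimum-jerk tail
swing to the opposite side (peak speed 2.2 rotations/s, peak position at
0.16 s) with a smaller out-and-back hip deflection (peak at 0.12 s).
Step-locked oscillations are gated off smoothly around the swing and the
forward speed drops to zero, mirroring the stopping seen after large
tilts.  Gaussian pixel noise and likelihood dropouts (below the 0.9
conditioning cutoff, with displaced coordinates) are applied last.
All randomness is driven by the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .biomech import TiltProfile
from .errors import ConfigError
from .io import (CentroidTrace, KeypointTable, TrialMeta,
                 write_centroid_trace, write_keypoint_table, write_manifest,
                 write_trial_meta)

SCORER = "synthetic"

REAR_BODYPARTS = ("tail_base", "tail_1", "tail_2",
                  "hip_left", "hip_right", "paw_left", "paw_right")
TOP_BODYPARTS = ("nose", "tail_base", "tail_1", "tail_2",
                 "paw_left", "paw_right")

#: Width (mm) -> (mean roll-plane tail angle deg, tail oscillation amplitude
#: deg), for a left-held tail.  Narrower ridges: tail held lower (below
#: horizontal on <= 5 mm) and swung over a larger range.
WIDTH_TAIL_MAP = {
    4.0: (75.0, 18.0),
    5.0: (82.0, 14.0),
    8.0: (100.0, 10.0),
    10.0: (105.0, 8.0),
    45.0: (110.0, 5.0),
}


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1] (0 -> 1, bell velocity with
    peak 1.875 at tau = 0.5)."""
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t ** 3 - 15 * t ** 4 + 6 * t ** 5


@dataclass
class SimConfig:
    """Parameters of one simulated ridge-crossing trial (units in names)."""

    ridge_width: float = 8.0            # mm
    ridge_length: float = 500.0         # mm
    frame_rate: float = 300.0           # frames/s
    trial_duration: float = 3.0         # s
    stride_frequency: float = 4.0       # Hz
    forward_speed: float = 150.0        # mm/s
    tail_side: str = "left"
    tail_mean_roll: float | None = None     # deg; None -> width map
    tail_osc_amplitude: float | None = None  # deg; None -> width map
    hip_osc_amplitude: float = 6.0      # deg
    tail_hip_phase: float = np.pi       # rad; anti-phase default
    tilt: TiltProfile | None = None
    swing_peak_speed: float = 2.2       # rotations/s at the swing peak
    tail_time_to_peak: float = 0.16     # s, onset -> peak tail position
    body_time_to_peak: float = 0.12     # s, onset -> peak hip position
    hip_tilt_deflection: float = 20.0   # deg, out-and-back hip response
    tail_return_fraction: float = 0.3   # partial return after the swing
    wander_mm: float = 1.0              # lateral wander s.d., mm
    noise_sd: float = 1.0               # px
    dropout_rate: float = 0.02          # fraction of samples
    slip_rate: float = 0.05             # per stride
    visibility_onset: float = 0.1       # s before the centroid is visible
    mm_per_pixel: dict = field(
        default_factory=lambda: {"rear": 0.25, "top": 0.5})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tail_side not in ("left", "right"):
            raise ConfigError("tail_side must be 'left' or 'right'")
        for name in ("ridge_width", "frame_rate", "trial_duration",
                     "stride_frequency", "swing_peak_speed",
                     "tail_time_to_peak", "body_time_to_peak"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.tail_mean_roll is None or self.tail_osc_amplitude is None:
            key = min(WIDTH_TAIL_MAP, key=lambda w: abs(w - self.ridge_width))
            mean, amp = WIDTH_TAIL_MAP[key]
            if self.tail_mean_roll is None:
                self.tail_mean_roll = mean
            if self.tail_osc_amplitude is None:
                self.tail_osc_amplitude = amp
        # tail segment must fit in the rear camera frame
        if 0.07 / self.mm_per_pixel["rear"] * 1000.0 > 4000.0:
            raise ConfigError("tail longer than the camera frame")

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_duration * self.frame_rate))


@dataclass
class GroundTruth:
    """Noise-free state of a simulated trial, consistent with the emitted
    tables by construction."""

    step_event_frames: np.ndarray      # contralateral-paw x peaks
    angles: dict                       # name -> deg array (all six)
    omega_tail: np.ndarray             # roll tail angular velocity, deg/s
    omega_body: np.ndarray             # hip angular velocity, deg/s
    tilt_onset: int | None
    slip_frames: np.ndarray
    laterality: str | None             # 'IL' | 'CL' | None
    config: SimConfig


def _swing_profile(cfg: SimConfig, t: np.ndarray,
                   tilt: TiltProfile) -> np.ndarray:
    """Signed roll-angle displacement (deg) of the tilt-evoked tail swing:
    minimum-jerk out to the full amplitude (peak position at
    tail_time_to_peak), then a partial minimum-jerk return."""
    peak_speed_deg = cfg.swing_peak_speed * 360.0
    T = cfg.tail_time_to_peak
    amplitude = peak_speed_deg * T / 1.875  # min-jerk peak-velocity relation
    t0 = tilt.onset / cfg.frame_rate
    out = _min_jerk((t - t0) / T)
    T_ret = 0.2
    ret = _min_jerk((t - t0 - T) / T_ret)
    # countering swing: opposite sign to the platform rotation (left = +)
    sign = -1.0 if tilt.direction == "left" else 1.0
    return sign * amplitude * (out - cfg.tail_return_fraction * ret)


def _hip_response_left(cfg: SimConfig, t: np.ndarray,
                       tilt: TiltProfile) -> np.ndarray:
    """Out-and-back hip deflection (deg) peaking at body_time_to_peak
    (left-tail convention; mirrored with the rest of the trial)."""
    T = cfg.body_time_to_peak
    t0 = tilt.onset / cfg.frame_rate
    out = _min_jerk((t - t0) / T)
    back = _min_jerk((t - t0 - T) / T)
    sign = -1.0 if tilt.direction == "left" else 1.0
    return sign * cfg.hip_tilt_deflection * (out - back)


def _gate(cfg: SimConfig, t: np.ndarray) -> np.ndarray:
    """Smooth 1 -> 0 -> 1 envelope suppressing stepping around the tilt."""
    if cfg.tilt is None:
        return np.ones_like(t)
    t0 = cfg.tilt.onset / cfg.frame_rate
    down = 0.05   # s, ramp off
    hold = 0.6    # s, paused
    up = 0.1      # s, ramp back on
    g = np.ones_like(t)
    g = np.where((t >= t0) & (t < t0 + down),
                 0.5 * (1 + np.cos(np.pi * (t - t0) / down)), g)
    g = np.where((t >= t0 + down) & (t < t0 + hold), 0.0, g)
    g = np.where((t >= t0 + hold) & (t < t0 + hold + up),
                 0.5 * (1 - np.cos(np.pi * (t - t0 - hold) / up)), g)
    return g


def _make_table(parts: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                order, view: str, frame_rate: float) -> KeypointTable:
    cols, data = [], []
    for bp in order:
        x, y, lik = parts[bp]
        for coord, arr in zip(("x", "y", "likelihood"), (x, y, lik)):
            cols.append((SCORER, bp, coord))
            data.append(arr)
    df = pd.DataFrame(np.column_stack(data),
                      columns=pd.MultiIndex.from_tuples(
                          cols, names=["scorer", "bodyparts", "coords"]))
    return KeypointTable(data=df, view=view, frame_rate=frame_rate)


def _add_noise(rng: np.random.Generator, parts: dict, cfg: SimConfig) -> dict:
    """Gaussian pixel jitter everywhere; dropouts get a sub-cutoff
    likelihood and a large coordinate excursion."""
    noisy = {}
    for bp, (x, y) in parts.items():
        n = len(x)
        xn = x + rng.normal(0.0, cfg.noise_sd, n)
        yn = y + rng.normal(0.0, cfg.noise_sd, n)
        lik = rng.uniform(0.95, 1.0, n)
        drop = rng.random(n) < cfg.dropout_rate
        lik[drop] = rng.uniform(0.0, 0.85, drop.sum())
        xn[drop] += rng.normal(0.0, 50.0, drop.sum())
        yn[drop] += rng.normal(0.0, 50.0, drop.sum())
        noisy[bp] = (xn, yn, lik)
    return noisy


def simulate_trial(cfg: SimConfig) -> tuple[KeypointTable, KeypointTable,
                                            CentroidTrace, TrialMeta,
                                            GroundTruth]:
    """Generate one trial: top and rear keypoint tables, centroid trace,
    metadata and ground truth.  Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    t = np.arange(n) / cfg.frame_rate
    phase = 2 * np.pi * cfg.stride_frequency * t
    gate = _gate(cfg, t)
    side = 1.0 if cfg.tail_side == "left" else -1.0

    # ----- ground-truth angles (deg) -------------------------------------
    # roll and hip are generated in the left-tail convention and mirrored
    # together for a right-held tail (roll about the vertical, hip about
    # horizontal), so mirrored trials keep mirrored lab-frame kinematics
    # and the tail-hip phase relation is side-invariant
    roll = (cfg.tail_mean_roll
            + cfg.tail_osc_amplitude * gate * np.sin(phase + cfg.tail_hip_phase))
    hip = 90.0 + cfg.hip_osc_amplitude * gate * np.sin(phase)
    if cfg.tilt is not None:
        swing_tilt = cfg.tilt if cfg.tail_side == "left" else TiltProfile(
            cfg.tilt.amplitude, cfg.tilt.duration,
            "left" if cfg.tilt.direction == "right" else "right",
            cfg.tilt.onset)
        roll = roll + _swing_profile(cfg, t, swing_tilt)
        hip = hip + _hip_response_left(cfg, t, swing_tilt)
    if cfg.tail_side == "right":
        roll = np.mod(360.0 - roll, 360.0)
        hip = 180.0 - hip

    yaw = -side * (45.0 + 0.5 * cfg.tail_osc_amplitude * gate
                   * np.sin(phase + cfg.tail_hip_phase))
    back = -side * 4.0 * gate * np.sin(phase)
    front = 3.0 * gate * np.sin(phase + np.pi / 3)
    from .kinematics import wrap_degrees
    tail_on_body = wrap_degrees(yaw - back)

    # ----- centroid (top view, px; ridge along +x, midline y = 0) --------
    mmpp_top = cfg.mm_per_pixel["top"]
    v_px = cfg.forward_speed * gate / mmpp_top / cfg.frame_rate
    cx = 40.0 + np.cumsum(v_px)
    white = rng.normal(0.0, 1.0, n)
    win = np.hanning(min(n, int(0.5 * cfg.frame_rate)))
    win /= win.sum()
    wander = np.convolve(np.pad(white, (len(win) // 2, len(win) - 1 - len(win) // 2),
                                mode="reflect"), win, mode="valid")
    sd = wander.std()
    wander = wander / sd * cfg.wander_mm if sd > 0 else wander
    sway = 0.5 * np.sin(phase)  # step-locked lateral sway, mm
    cy = (wander + sway) / mmpp_top
    visibility = t >= cfg.visibility_onset
    centroid = CentroidTrace(cx, cy, visibility, cfg.frame_rate)

    # ----- rear view keypoints (px) --------------------------------------
    mmpp_rear = cfg.mm_per_pixel["rear"]
    seg_px = 23.0 / mmpp_rear  # initial tail segment, ~1/3 of 7 cm
    roll_rad = np.radians(roll)
    base = np.array([0.0, 40.0])
    tail_dir = np.column_stack([np.sin(roll_rad), -np.cos(roll_rad)])
    tail_base = np.tile(base, (n, 1))
    tail_1 = tail_base + seg_px * tail_dir
    tail_2 = tail_1 + seg_px * tail_dir
    hip_rad = np.radians(hip)
    hip_c = np.array([0.0, 50.0])
    hip_half = (20.0 / mmpp_rear) / 2.0
    hip_vec = np.column_stack([np.sin(hip_rad), np.cos(hip_rad)])
    hip_left = hip_c - hip_half * hip_vec
    hip_right = hip_c + hip_half * hip_vec
    paw_amp = 12.0
    paw_left_x = -30.0 + paw_amp * gate * np.sin(phase)
    paw_right_x = 30.0 + paw_amp * gate * np.sin(phase + np.pi)
    paw_y = np.full(n, 5.0)
    rear_clean = {
        "tail_base": (tail_base[:, 0], tail_base[:, 1]),
        "tail_1": (tail_1[:, 0], tail_1[:, 1]),
        "tail_2": (tail_2[:, 0], tail_2[:, 1]),
        "hip_left": (hip_left[:, 0], hip_left[:, 1]),
        "hip_right": (hip_right[:, 0], hip_right[:, 1]),
        "paw_left": (paw_left_x, paw_y),
        "paw_right": (paw_right_x, paw_y),
    }

    # ----- top view keypoints (px) ---------------------------------------
    yaw_rad = np.radians(yaw)
    back_rad = np.radians(back)
    front_rad = np.radians(front)
    d_body = 30.0 / mmpp_top   # centroid -> tail base distance
    d_nose = 35.0 / mmpp_top
    cen = np.column_stack([cx, cy])
    base_top = cen - d_body * np.column_stack([np.cos(back_rad),
                                               np.sin(back_rad)])
    nose = cen + d_nose * np.column_stack([np.cos(front_rad),
                                           np.sin(front_rad)])
    seg_top = 23.0 / mmpp_top
    tail_dir_top = np.column_stack([-np.cos(yaw_rad), -np.sin(yaw_rad)])
    tail_1_top = base_top + seg_top * tail_dir_top
    tail_2_top = tail_1_top + seg_top * tail_dir_top
    paw_dx = 15.0 / mmpp_top
    paw_osc = (10.0 / mmpp_top) * gate
    top_clean = {
        "nose": (nose[:, 0], nose[:, 1]),
        "tail_base": (base_top[:, 0], base_top[:, 1]),
        "tail_1": (tail_1_top[:, 0], tail_1_top[:, 1]),
        "tail_2": (tail_2_top[:, 0], tail_2_top[:, 1]),
        "paw_left": (cx - paw_dx + paw_osc * np.sin(phase),
                     cy + 4.0 / mmpp_top),
        "paw_right": (cx - paw_dx + paw_osc * np.sin(phase + np.pi),
                      cy - 4.0 / mmpp_top),
    }

    rear = _make_table(_add_noise(rng, rear_clean, cfg), REAR_BODYPARTS,
                       "rear", cfg.frame_rate)
    top = _make_table(_add_noise(rng, top_clean, cfg), TOP_BODYPARTS,
                      "top", cfg.frame_rate)

    # ----- ground truth ---------------------------------------------------
    contra_phase = phase + (np.pi if cfg.tail_side == "left" else 0.0)
    # peaks of sin(contra_phase): contra_phase = pi/2 + 2 pi k
    k = np.arange(0, int(cfg.stride_frequency * cfg.trial_duration) + 1)
    peak_t = (np.pi / 2 + 2 * np.pi * k
              - (np.pi if cfg.tail_side == "left" else 0.0)) \
        / (2 * np.pi * cfg.stride_frequency)
    peak_frames = np.round(peak_t * cfg.frame_rate).astype(int)
    peak_frames = peak_frames[(peak_frames >= 0) & (peak_frames < n)]
    if cfg.tilt is not None:  # steps suppressed while stepping is gated off
        keep = gate[peak_frames] > 0.5
        peak_frames = peak_frames[keep]

    n_strides = max(0, len(peak_frames) - 1)
    slips = peak_frames[1:][rng.random(n_strides) < cfg.slip_rate] \
        if n_strides else np.array([], dtype=int)

    laterality = None
    if cfg.tilt is not None:
        laterality = "IL" if cfg.tilt.direction == cfg.tail_side else "CL"

    truth = GroundTruth(
        step_event_frames=peak_frames,
        angles={"roll_tail": np.mod(roll, 360.0), "yaw_tail": yaw,
                "hip": hip, "back": back, "front": front,
                "tail_on_body": tail_on_body},
        omega_tail=np.gradient(np.unwrap(roll, period=360.0)) * cfg.frame_rate,
        omega_body=np.gradient(hip) * cfg.frame_rate,
        tilt_onset=None if cfg.tilt is None else cfg.tilt.onset,
        slip_frames=slips,
        laterality=laterality,
        config=cfg,
    )

    meta = TrialMeta(
        animal_id="sim",
        ridge_width=cfg.ridge_width,
        ridge_length=cfg.ridge_length,
        tilt_present=cfg.tilt is not None,
        tilt_direction="none" if cfg.tilt is None else cfg.tilt.direction,
        tilt_amplitude=0.0 if cfg.tilt is None else cfg.tilt.amplitude,
        tilt_duration=0.0 if cfg.tilt is None else cfg.tilt.duration,
        tilt_onset=-1 if cfg.tilt is None else cfg.tilt.onset,
        mm_per_pixel=dict(cfg.mm_per_pixel),
    )
    return top, rear, centroid, meta, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: The study's tilt conditions: amplitude deg -> ramp duration s (constant
#: tilt angular velocity across conditions).
TILT_CONDITIONS = {10.0: 0.150, 20.0: 0.190, 30.0: 0.230}


def default_conditions(widths=(4.0, 5.0, 8.0, 10.0),
                       trial_types=("no_tilt", "tilt")) -> list[dict]:
    """Width x trial-type grid (tilt trials use the 20 deg / 190 ms baseline)."""
    return [{"ridge_width": w, "trial_type": tt}
            for w in widths for tt in trial_types]


def simulate_cohort(n_animals: int, trials_per_condition: int,
                    conditions: list[dict] | None = None,
                    seed: int = 0,
                    outdir: str | Path | None = None,
                    jitter: float = 0.03,
                    tilt_amplitude: float = 20.0,
                    trial_duration: float = 3.0) -> list[dict]:
    """Simulate a cohort and return its trial manifest.

    Per-animal parameter jitter is a small multiplicative Gaussian
    perturbation (s.d. ``jitter``) of oscillation amplitudes and speeds;
    condition order is rotated per animal (Latin-square style).  With
    ``outdir`` set, keypoint tables, centroid traces, metadata and ground
    truth are written to disk and the manifest records point at the files;
    otherwise the records carry the in-memory objects under ``"objects"``.
    """
    if n_animals < 1 or trials_per_condition < 1:
        raise ConfigError("counts must be >= 1")
    if conditions is None:
        conditions = default_conditions()
    root = np.random.default_rng(seed)
    manifest: list[dict] = []
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    for a in range(n_animals):
        animal = f"mouse{a:02d}"
        arng = np.random.default_rng(root.integers(2 ** 31))
        scale = dict(
            amp=1.0 + jitter * arng.standard_normal(),
            speed=1.0 + jitter * arng.standard_normal(),
            stride=1.0 + jitter * arng.standard_normal(),
        )
        tail_side = "left" if arng.random() < 0.5 else "right"
        ordered = conditions[a % len(conditions):] + conditions[:a % len(conditions)]
        for cond in ordered:
            for rep in range(trials_per_condition):
                trial_seed = int(root.integers(2 ** 31))
                tilt = None
                if cond["trial_type"] == "tilt":
                    duration = TILT_CONDITIONS.get(tilt_amplitude, 0.19)
                    direction = "left" if arng.random() < 0.5 else "right"
                    # onset randomly timed (anticipation prevention), kept
                    # early enough for the response window to fit
                    onset = int(arng.integers(int(0.35 * trial_duration * 300),
                                              int(0.50 * trial_duration * 300)))
                    tilt = TiltProfile(amplitude=tilt_amplitude,
                                       duration=duration,
                                       direction=direction,
                                       onset=onset)
                cfg = SimConfig(
                    ridge_width=cond["ridge_width"],
                    trial_duration=trial_duration,
                    tail_side=tail_side,
                    tilt=tilt,
                    swing_peak_speed=2.2 * scale["speed"],
                    stride_frequency=4.0 * scale["stride"],
                    hip_osc_amplitude=6.0 * scale["amp"],
                    seed=trial_seed,
                )
                if cfg.tail_osc_amplitude is not None:
                    cfg.tail_osc_amplitude *= scale["amp"]
                top, rear, centroid, meta, truth = simulate_trial(cfg)
                meta.animal_id = animal
                name = (f"{animal}_w{cond['ridge_width']:g}"
                        f"_{cond['trial_type']}_{rep}")
                record = {"trial_id": name, "animal_id": animal,
                          "ridge_width": cond["ridge_width"],
                          "trial_type": cond["trial_type"],
                          "seed": trial_seed}
                if outdir is None:
                    record["objects"] = {"top": top, "rear": rear,
                                         "centroid": centroid, "meta": meta,
                                         "truth": truth}
                else:
                    paths = {
                        "top": f"{name}_top.csv",
                        "rear": f"{name}_rear.csv",
                        "centroid": f"{name}_centroid.csv",
                        "meta": f"{name}_meta.yaml",
                        "truth": f"{name}_truth.json",
                    }
                    write_keypoint_table(top, outdir / paths["top"])
                    write_keypoint_table(rear, outdir / paths["rear"])
                    write_centroid_trace(centroid, outdir / paths["centroid"])
                    write_trial_meta(meta, outdir / paths["meta"])
                    with open(outdir / paths["truth"], "w") as fh:
                        json.dump(ground_truth_to_dict(truth), fh)
                    record["files"] = paths
                manifest.append(record)
    if outdir is not None:
        write_manifest([{k: v for k, v in r.items() if k != "objects"}
                        for r in manifest], outdir / "manifest.yaml")
    return manifest


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    """JSON-serializable ground-truth sidecar (config flattened)."""
    cfg = asdict(truth.config)
    cfg["tilt"] = None if truth.config.tilt is None else {
        "amplitude": truth.config.tilt.amplitude,
        "duration": truth.config.tilt.duration,
        "direction": truth.config.tilt.direction,
        "onset": truth.config.tilt.onset,
    }
    return {
        "step_event_frames": truth.step_event_frames.tolist(),
        "tilt_onset": truth.tilt_onset,
        "slip_frames": truth.slip_frames.tolist(),
        "laterality": truth.laterality,
        "config": cfg,
    }
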