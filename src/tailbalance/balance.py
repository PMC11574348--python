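"""Ridge-traversing balance performance from the top-view centroid.

Five metrics: traversing speed (endpoint displacement over time, reported
with and without stop episodes), stop episodes (forward speed below an
immobility threshold, default 1 mm/s), time the centre of mass spends
outside the base of support (the ridge edges), mean absolute lateral
deviation from the midline, and centrality (1 on the midline, 0 at the
edge, clipped at 0 beyond it).  Slip counts are consumed as manual labels,
never computed from video.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import CentroidTrace, TrialMeta, hanning_smooth

#: The ridge runs along +x in top view; lateral offset is the y distance
#: from the midline at y = 0 (in math coordinates).
RIDGE_MIDLINE_Y = 0.0


@dataclass
class StopEpisodes:
    count: int
    total_duration: float          # s
    episodes: list[tuple[int, int]]  # [start, stop) frame runs


@dataclass
class BalanceReport:
    traversing_speed: float          # mm/s, stop time included
    traversing_speed_moving: float   # mm/s, stop time excluded
    stop_count: int
    stop_duration: float             # s
    time_outside_bos: float          # s
    lateral_movement: float          # mm
    centrality: float                # [0, 1]
    slip_count: int | None = None    # manual label, optional


def _visible(centroid: CentroidTrace) -> np.ndarray:
    vis = np.flatnonzero(centroid.visibility)
    if vis.size < 2:
        raise ParameterError("balance metrics need >= 2 visible frames")
    return vis


def _lateral_offset_mm(centroid: CentroidTrace, meta: TrialMeta) -> np.ndarray:
    mmpp = meta.mm_per_pixel["top"]
    return (centroid.y - RIDGE_MIDLINE_Y) * mmpp


def traversing_speed(centroid: CentroidTrace, meta: TrialMeta) -> float:
    """Forward (along-ridge) distance covered divided by the time taken,
    mm/s, between the first and last visible frame."""
    vis = _visible(centroid)
    mmpp = meta.mm_per_pixel["top"]
    dist = (centroid.x[vis[-1]] - centroid.x[vis[0]]) * mmpp
    elapsed = (vis[-1] - vis[0]) / centroid.frame_rate
    return float(dist / elapsed)


def forward_speed_series(centroid: CentroidTrace, meta: TrialMeta,
                         smoothing_window: int = 10) -> np.ndarray:
    """Instantaneous forward speed (mm/s) from the centroid gradient, then
    Hanning-smoothed (used for stop detection; distinct from the endpoint
    traversing speed).  Smoothing the speed rather than the position keeps
    a steady ramp's speed unbiased at the trace edges."""
    mmpp = meta.mm_per_pixel["top"]
    speed = np.gradient(centroid.x * mmpp) * centroid.frame_rate
    if smoothing_window > 1 and len(speed) >= smoothing_window:
        speed = hanning_smooth(speed, smoothing_window)
    return speed


def detect_stops(speed: np.ndarray, frame_rate: float,
                 threshold: float = 1.0) -> StopEpisodes:
    """Maximal runs of frames with forward speed strictly below ``threshold``
    (mm/s; the immobility threshold)."""
    if threshold <= 0:
        raise ParameterError("stop threshold must be positive")
    speed = np.asarray(speed, dtype=float)
    below = speed < threshold
    episodes: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        episodes.append((int(start), int(stop)))
    total = sum(stop - start for start, stop in episodes) / frame_rate
    return StopEpisodes(count=len(episodes), total_duration=float(total),
                        episodes=episodes)


def time_outside_bos(centroid: CentroidTrace, meta: TrialMeta) -> float:
    """Total time (s) the centroid lies strictly outside the ridge edges."""
    off = _lateral_offset_mm(centroid, meta)
    vis = centroid.visibility
    outside = (np.abs(off) > meta.ridge_width / 2.0) & vis
    return float(outside.sum() / centroid.frame_rate)


def lateral_movement(centroid: CentroidTrace, meta: TrialMeta) -> float:
    """Mean absolute lateral distance (mm) of the centroid from the midline,
    over visible frames."""
    off = _lateral_offset_mm(centroid, meta)
    return float(np.abs(off[centroid.visibility]).mean())


def centrality(centroid: CentroidTrace, meta: TrialMeta) -> float:
    """Mean of 1 - |lateral offset| / (width/2) over visible frames, clipped
    at 0 beyond the edge; 1 = centroid on the midline, 0 = on the edge."""
    off = _lateral_offset_mm(centroid, meta)
    c = np.clip(1.0 - np.abs(off) / (meta.ridge_width / 2.0), 0.0, None)
    return float(c[centroid.visibility].mean())


def balance_report(centroid: CentroidTrace, meta: TrialMeta,
                   stop_threshold: float = 1.0,
                   smoothing_window: int = 10,
                   slip_count: int | None = None) -> BalanceReport:
    """All balance metrics for one trial.

    The trial-level traversing speed uses endpoint displacement; the
    stop-time-excluded variant divides the same displacement by the time
    spent above the immobility threshold.
    """
    vis = _visible(centroid)
    speed = traversing_speed(centroid, meta)
    inst = forward_speed_series(centroid, meta, smoothing_window)
    stops = detect_stops(inst[vis[0]:vis[-1] + 1], centroid.frame_rate,
                         stop_threshold)
    elapsed = (vis[-1] - vis[0]) / centroid.frame_rate
    moving_time = elapsed - stops.total_duration
    mmpp = meta.mm_per_pixel["top"]
    dist = (centroid.x[vis[-1]] - centroid.x[vis[0]]) * mmpp
    speed_moving = float(dist / moving_time) if moving_time > 0 else np.nan
    return BalanceReport(
        traversing_speed=speed,
        traversing_speed_moving=speed_moving,
        stop_count=stops.count,
        stop_duration=stops.total_duration,
        time_outside_bos=time_outside_bos(centroid, meta),
        lateral_movement=lateral_movement(centroid, meta),
        centrality=centrality(centroid, meta),
        slip_count=slip_count,
    )
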