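"""Step-event detection and step-cycle alignment.

A step cycle is anchored on the peak of the x-excursion of the hind paw
contralateral to the (canonical) tail side.  Epochs of any per-frame trace
are cut around those peaks and summarised per cycle (mean position and
range of motion), matching how tail and hip traces are pooled across
animals per ridge width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ParameterError, ShapeError


@dataclass
class StepEventSeries:
    """Frames of x-projection peaks of one hind paw, with the median stride."""

    paw: str
    event_frames: np.ndarray
    stride_period_frames: float

    def __post_init__(self) -> None:
        self.event_frames = np.asarray(self.event_frames, dtype=int)
        if self.event_frames.size and np.any(np.diff(self.event_frames) <= 0):
            raise ShapeError("event frames must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.event_frames.size


@dataclass
class StepCycleSet:
    """Fixed-length windows of a trace centered on step events.

    ``epochs`` has shape (n_epochs, 2*halfwidth + 1); epochs that would be
    clipped by the trial edges are excluded.  ``bin_times`` gives seconds
    relative to the swing peak.
    """

    epochs: np.ndarray
    window_halfwidth: int
    event_frames: np.ndarray
    frame_rate: float = 300.0

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        self.event_frames = np.asarray(self.event_frames, dtype=int)
        if self.epochs.size and self.epochs.shape[1] != 2 * self.window_halfwidth + 1:
            raise ShapeError("epoch length must equal 2*halfwidth + 1")

    @property
    def n_epochs(self) -> int:
        return 0 if self.epochs.size == 0 else self.epochs.shape[0]

    @property
    def bin_times(self) -> np.ndarray:
        h = self.window_halfwidth
        return np.arange(-h, h + 1) / self.frame_rate


def detect_step_peaks(paw_x: np.ndarray,
                      min_separation: int | None = None,
                      min_prominence: float | None = None,
                      expected_stride_frames: float = 75.0,
                      paw: str = "contralateral") -> StepEventSeries:
    """Step events as local maxima of the (smoothed) paw x series.

    Defaults: ``min_separation`` = half the expected stride period;
    ``min_prominence`` = 25% of the interquartile range of the series.
    Finding no peak yields an empty series with a warning (the trial is then
    excluded from cycle analyses, never silently).
    """
    paw_x = np.asarray(paw_x, dtype=float)
    if min_separation is None:
        min_separation = max(1, int(round(0.5 * expected_stride_frames)))
    if min_separation < 1:
        raise ParameterError("min_separation must be >= 1")
    if min_prominence is None:
        q75, q25 = np.percentile(paw_x, [75, 25])
        min_prominence = 0.25 * (q75 - q25)
    peaks, _ = find_peaks(paw_x, distance=min_separation,
                          prominence=min_prominence if min_prominence > 0 else None)
    if peaks.size == 0:
        warnings.warn("no step peaks found; trial excluded from cycle analyses")
        return StepEventSeries(paw, np.array([], dtype=int), np.nan)
    period = float(np.median(np.diff(peaks))) if peaks.size > 1 else np.nan
    return StepEventSeries(paw, peaks, period)


def align_epochs(trace: np.ndarray, events: StepEventSeries,
                 halfwidth: int, frame_rate: float = 300.0) -> StepCycleSet:
    """Cut one fixed-length epoch per step event fully inside the trace.

    Epoch center = event frame; events closer than ``halfwidth`` to either
    trial edge are dropped.  An all-clipped result is an empty set with a
    warning.
    """
    if halfwidth < 1:
        raise ParameterError("halfwidth must be >= 1")
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    kept, rows = [], []
    for e in events.event_frames:
        if e - halfwidth >= 0 and e + halfwidth < n:
            kept.append(int(e))
            rows.append(trace[e - halfwidth:e + halfwidth + 1])
    if not rows:
        warnings.warn("all epochs clipped at trial edges; empty cycle set")
        return StepCycleSet(np.empty((0, 2 * halfwidth + 1)), halfwidth,
                            np.array([], dtype=int), frame_rate)
    return StepCycleSet(np.vstack(rows), halfwidth, np.array(kept), frame_rate)


def cycle_stats(cycles: StepCycleSet) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-epoch mean position and range (max - min), plus trial averages.

    Returns a tidy frame (one row per epoch) and the per-trial averages as a
    dict with keys ``mean_position`` and ``range``.
    """
    if cycles.n_epochs == 0:
        raise ParameterError("cycle_stats needs at least one epoch")
    means = cycles.epochs.mean(axis=1)
    ranges = cycles.epochs.max(axis=1) - cycles.epochs.min(axis=1)
    per_epoch = pd.DataFrame({
        "epoch": np.arange(cycles.n_epochs),
        "event_frame": cycles.event_frames,
        "mean_position": means,
        "range": ranges,
    })
    summary = {"mean_position": float(means.mean()),
               "range": float(ranges.mean())}
    return per_epoch, summary
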