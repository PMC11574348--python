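"""Keypoint-table and trial-metadata I/O plus trace conditioning.

Reads the multi-row-header table dialect emitted by common markerless
trackers (a ``scorer / bodyparts / coords`` CSV header, or the equivalent
HDF5 layout), applies the likelihood cutoff with gap interpolation, smooths
traces with a normalized Hanning window, aligns the rear and top camera
streams on centroid visibility, and extracts the centered analysis window.

Coordinate convention: files store image coordinates (origin top-left,
y increasing downward).  On read the y axis is flipped so that all
in-memory math is done with y increasing upward; on write it is flipped
back, so a write -> read round trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    AlignmentError,
    ConfigError,
    EmptyROIError,
    FormatError,
    IntegrityError,
    ParameterError,
    UnusableBodypartError,
    WindowError,
)

COORDS = ("x", "y", "likelihood")

#: Ridge widths used in the study design, mm (45 mm is the "flat surface" control).
RIDGE_WIDTHS_MM = (4.0, 5.0, 8.0, 10.0, 45.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class KeypointTable:
    """Per-frame (x, y, likelihood) for named bodyparts from one camera view.

    ``data`` holds a frame-indexed DataFrame with a three-level column
    MultiIndex ``(scorer, bodypart, coord)``; coordinates are in pixels with
    y up (math convention), likelihood in [0, 1].  Missing samples are NaN.
    """

    data: pd.DataFrame
    view: str
    frame_rate: float = 300.0

    def __post_init__(self) -> None:
        if self.view not in ("rear", "top"):
            raise ConfigError(f"unknown camera view {self.view!r}")
        if not self.frame_rate > 0:
            raise IntegrityError("frame_rate must be positive")
        lik = self.data.xs("likelihood", axis=1, level=-1)
        vals = lik.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise IntegrityError("likelihood values outside [0, 1]")

    @property
    def scorer(self) -> str:
        return self.data.columns.get_level_values(0)[0]

    @property
    def bodyparts(self) -> list[str]:
        seen: list[str] = []
        for bp in self.data.columns.get_level_values(1):
            if bp not in seen:
                seen.append(bp)
        return seen

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def _col(self, bodypart: str, coord: str) -> np.ndarray:
        return self.data[(self.scorer, bodypart, coord)].to_numpy(dtype=float)

    def x(self, bodypart: str) -> np.ndarray:
        return self._col(bodypart, "x")

    def y(self, bodypart: str) -> np.ndarray:
        return self._col(bodypart, "y")

    def likelihood(self, bodypart: str) -> np.ndarray:
        return self._col(bodypart, "likelihood")

    def point(self, bodypart: str) -> np.ndarray:
        """(n_frames, 2) array of x, y for one bodypart."""
        return np.column_stack([self.x(bodypart), self.y(bodypart)])

    def crop(self, start: int, stop: int | None = None) -> "KeypointTable":
        sub = self.data.iloc[start:stop].reset_index(drop=True)
        return replace(self, data=sub)


@dataclass
class CentroidTrace:
    """Top-view body-silhouette centroid per frame, with a visibility flag."""

    x: np.ndarray
    y: np.ndarray
    visibility: np.ndarray
    frame_rate: float = 300.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.visibility = np.asarray(self.visibility, dtype=bool)
        if not (len(self.x) == len(self.y) == len(self.visibility)):
            raise IntegrityError("centroid trace arrays must share one length")

    @property
    def n_frames(self) -> int:
        return len(self.x)

    def crop(self, start: int, stop: int | None = None) -> "CentroidTrace":
        sl = slice(start, stop)
        return CentroidTrace(self.x[sl], self.y[sl], self.visibility[sl],
                             self.frame_rate)


@dataclass
class TrialMeta:
    """Per-trial metadata: geometry, tilt profile parameters and calibration.

    ``mm_per_pixel`` maps each view name to its scalar calibration,
    obtainable from the known 500 mm ridge length in the top view.
    """

    animal_id: str
    ridge_width: float
    ridge_length: float = 500.0
    tilt_present: bool = False
    tilt_direction: str = "none"
    tilt_amplitude: float = 0.0
    tilt_duration: float = 0.0
    tilt_onset: int = -1
    mm_per_pixel: Mapping[str, float] = field(
        default_factory=lambda: {"rear": 0.25, "top": 0.5})

    def __post_init__(self) -> None:
        if self.ridge_width <= 0:
            raise IntegrityError("ridge_width must be positive")
        if any(v <= 0 for v in self.mm_per_pixel.values()):
            raise IntegrityError("mm_per_pixel must be positive")
        if self.tilt_present:
            if self.tilt_direction not in ("left", "right"):
                raise IntegrityError(
                    "tilt_present requires tilt_direction left or right")
            if self.tilt_duration <= 0:
                raise IntegrityError("tilt_present requires tilt_duration > 0")
        elif self.tilt_direction != "none":
            raise IntegrityError("absent tilt requires tilt_direction 'none'")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["mm_per_pixel"] = dict(self.mm_per_pixel)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialMeta":
        return cls(**dict(d))


@dataclass
class AlignedTrial:
    """Two-view streams cropped to a common frame index (frame 0 = first
    centroid-visible frame)."""

    top: KeypointTable
    rear: KeypointTable
    centroid: CentroidTrace
    start_frame: int  # original frame index of aligned frame 0


# ---------------------------------------------------------------------------
# table reading / writing
# ---------------------------------------------------------------------------

def _validate_columns(df: pd.DataFrame, path: str) -> None:
    if df.columns.nlevels != 3:
        raise FormatError(
            f"{path}: expected a 3-row header (scorer/bodyparts/coords), "
            f"found {df.columns.nlevels} level(s)")
    coords = df.columns.get_level_values(-1)
    bad = sorted(set(coords) - set(COORDS))
    if bad:
        raise FormatError(
            f"{path}: coords header row contains unknown labels {bad}")
    for bp in df.columns.get_level_values(1).unique():
        sub = df.xs(bp, axis=1, level=1)
        if set(sub.columns.get_level_values(-1)) != set(COORDS):
            raise FormatError(
                f"{path}: bodyparts header row: {bp!r} lacks x/y/likelihood")


def _flip_y(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    ys = [c for c in out.columns if c[-1] == "y"]
    out[ys] = -out[ys]
    return out


def read_keypoint_table(path: str | Path, view: str,
                        frame_rate: float = 300.0) -> KeypointTable:
    """Read a keypoint table (CSV or HDF5 tracker dialect) for one view.

    Missing cells stay NaN.  The y axis is flipped to the math convention.
    Raises :class:`FormatError` for a malformed header and
    :class:`IntegrityError` for out-of-bounds likelihoods.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf", ".hdf5"):
        obj = pd.read_hdf(path)
        if not isinstance(obj, pd.DataFrame):
            raise FormatError(f"{path}: HDF file does not hold a table")
        df = obj
    else:
        try:
            df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                             float_precision="round_trip")
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"{path}: cannot parse 3-row header ({exc})")
    _validate_columns(df, str(path))
    df = df.astype(float).reset_index(drop=True)
    return KeypointTable(data=_flip_y(df), view=view, frame_rate=frame_rate)


def write_keypoint_table(table: KeypointTable, path: str | Path) -> None:
    """Write a table back to the tracker dialect (format from the suffix)."""
    path = Path(path)
    df = _flip_y(table.data)  # back to image coordinates
    if path.suffix.lower() in (".h5", ".hdf", ".hdf5"):
        df.to_hdf(path, key="df_with_missing", mode="w")
    else:
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(path, float_format="%.17g")


def read_trial_meta(path: str | Path) -> TrialMeta:
    """Read one trial's metadata record from a YAML file."""
    with open(path) as fh:
        return TrialMeta.from_dict(yaml.safe_load(fh))


def write_trial_meta(meta: TrialMeta, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(meta.to_dict(), fh, sort_keys=True)


def read_centroid_trace(path: str | Path,
                        frame_rate: float = 300.0) -> CentroidTrace:
    df = pd.read_csv(path)
    return CentroidTrace(df["x"].to_numpy(), -df["y"].to_numpy(),
                         df["visible"].to_numpy(dtype=bool), frame_rate)


def write_centroid_trace(trace: CentroidTrace, path: str | Path) -> None:
    pd.DataFrame({"x": trace.x, "y": -trace.y,
                  "visible": trace.visibility.astype(int)}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def apply_likelihood_cutoff(table: KeypointTable, cutoff: float = 0.9,
                            mode: str = "interpolate",
                            ) -> tuple[KeypointTable, dict[str, int]]:
    """Condition coordinates with a likelihood cutoff.

    Samples with likelihood strictly below ``cutoff`` (and samples with
    missing coordinates) are invalidated.  ``mode='interpolate'`` (default)
    replaces them by linear interpolation between the nearest valid
    neighbours, extending the nearest valid value over edge gaps;
    ``mode='hold'`` holds the previous valid value; ``mode='drop'`` leaves
    them NaN.  Returns the conditioned table and a per-bodypart count of
    replaced samples.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ParameterError("cutoff must lie in [0, 1]")
    if mode not in ("interpolate", "hold", "drop"):
        raise ConfigError(f"unknown conditioning mode {mode!r}")

    df = table.data.copy()
    scorer = table.scorer
    replaced: dict[str, int] = {}
    frames = np.arange(table.n_frames, dtype=float)
    for bp in table.bodyparts:
        lik = table.likelihood(bp)
        x = table.x(bp)
        y = table.y(bp)
        bad = (lik < cutoff) | ~np.isfinite(x) | ~np.isfinite(y)
        replaced[bp] = int(bad.sum())
        if not bad.any():
            continue
        good = ~bad
        if not good.any():
            raise UnusableBodypartError(
                f"bodypart {bp!r}: no sample at or above cutoff {cutoff}")
        if mode == "drop":
            x = np.where(bad, np.nan, x)
            y = np.where(bad, np.nan, y)
        elif mode == "hold":
            idx = np.where(good, frames, -1.0)
            last = np.maximum.accumulate(idx)
            first_good = int(np.flatnonzero(good)[0])
            last = np.where(last < 0, first_good, last).astype(int)
            x, y = x[last], y[last]
        else:  # linear interpolation, edges clamped to nearest valid
            x = np.interp(frames, frames[good], x[good])
            y = np.interp(frames, frames[good], y[good])
        df[(scorer, bp, "x")] = x
        df[(scorer, bp, "y")] = y
    return replace(table, data=df), replaced


def hanning_smooth(series: np.ndarray, window: int = 10) -> np.ndarray:
    """Smooth a 1-D series with a unit-sum Hanning window of ``window`` frames.

    Edges are reflect-padded so the output has the input's length and no
    edge attenuation; ``window`` of 1 or 2 is the identity (a Hanning kernel
    that short has no interior weight).
    """
    series = np.asarray(series, dtype=float)
    if window < 1:
        raise ParameterError("window must be >= 1")
    if series.ndim != 1:
        raise ParameterError("hanning_smooth expects a 1-D series")
    if window > series.size:
        raise ParameterError(
            f"window {window} exceeds series length {series.size}")
    if window <= 2:
        return series.copy()
    kernel = np.hanning(window)
    kernel /= kernel.sum()
    left = window // 2
    right = window - 1 - left
    padded = np.pad(series, (left, right), mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def extract_centered_window(series: np.ndarray, n: int = 500,
                            return_start: bool = False):
    """Return the ``n`` samples centered on the series midpoint.

    With an odd surplus the extra sample is dropped from the end.  Works on
    the first axis of any array.  Raises :class:`WindowError` if the series
    is shorter than ``n``.
    """
    series = np.asarray(series)
    length = series.shape[0]
    if length < n:
        raise WindowError(f"series of length {length} shorter than n={n}")
    start = (length - n) // 2
    out = series[start:start + n]
    return (out, start) if return_start else out


def align_on_visibility(top: KeypointTable, rear: KeypointTable,
                        centroid: CentroidTrace) -> AlignedTrial:
    """Crop both camera streams so frame 0 is the first centroid-visible
    frame; trailing frames beyond the shorter stream are dropped."""
    visible = np.flatnonzero(centroid.visibility)
    if visible.size == 0:
        raise AlignmentError("centroid never becomes visible")
    start = int(visible[0])
    n = min(top.n_frames, rear.n_frames, centroid.n_frames) - start
    if n <= 0:
        raise AlignmentError("no overlapping frames after visibility onset")
    return AlignedTrial(top=top.crop(start, start + n),
                        rear=rear.crop(start, start + n),
                        centroid=centroid.crop(start, start + n),
                        start_frame=start)


def centroid_from_mask(mask: np.ndarray) -> tuple[float, float]:
    """Mean (x, y) of foreground pixels of a binary silhouette mask.

    The mask is indexed [row, col]; the returned point is (x=col, y=row).
    An empty mask raises :class:`EmptyROIError` (maps to a non-visible frame).
    """
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyROIError("mask has no foreground pixel")
    return float(cols.mean()), float(rows.mean())


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> list[dict]:
    """Read a trial manifest (YAML list of records with file paths + meta)."""
    with open(path) as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise FormatError(f"{path}: manifest must be a list of trial records")
    return records


def write_manifest(records: Sequence[Mapping], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(list(records), fh, sort_keys=False)
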