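"""Tail-body momentum cross-correlogram over step-cycle epochs.

For each pair of time bins (i, j) relative to the contralateral-paw swing
peak, C[i, j] is the Pearson correlation, across epochs, of tail momentum
at bin i against body momentum at bin j.  Hotspots and coldspots are the
largest 8-connected components of cells in the extreme upper/lower
percentile tails of the cell distribution; the diagonal C[i, i] tracks the
instantaneous (zero-lag) coupling through the step cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, ParameterError, ShapeError
from .gait import StepCycleSet


@dataclass
class CrossCorrelogram:
    """Time-bin x time-bin correlation matrix; rows = tail bins, columns =
    body bins; undefined (zero-variance) cells are NaN."""

    matrix: np.ndarray
    n_trials: int
    bin_times: np.ndarray
    mode: str = "across_trials"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ShapeError("correlogram must be square")
        finite = self.matrix[np.isfinite(self.matrix)]
        if finite.size and (np.abs(finite) > 1.0 + 1e-9).any():
            raise ShapeError("correlation values must lie in [-1, 1]")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ExtremeRegion:
    """The largest contiguous block of extreme-tail correlogram cells."""

    kind: str                 # 'hotspot' | 'coldspot'
    cells: frozenset          # of (i, j) index pairs
    mean_value: float

    @property
    def size(self) -> int:
        return len(self.cells)


def _standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize across epochs; returns (z, defined-column mask)."""
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    ok = sd > 0
    z = np.zeros_like(mat)
    z[:, ok] = (mat[:, ok] - mean[ok]) / sd[ok]
    return z, ok


def build_correlogram(tail_epochs: StepCycleSet, body_epochs: StepCycleSet,
                      mode: str = "across_trials") -> CrossCorrelogram:
    """Correlate tail and body momentum bins over step-cycle epochs.

    ``mode='across_trials'`` (default) computes the Pearson correlation of
    the two bins across epochs.  ``mode='within_trial_lag'`` standardizes
    each epoch over time instead and averages the bin-pair products over
    epochs, a within-trial reading of the same matrix.
    """
    if mode not in ("across_trials", "within_trial_lag"):
        raise ConfigError(f"unknown correlogram mode {mode!r}")
    te, be = tail_epochs.epochs, body_epochs.epochs
    if te.shape != be.shape:
        raise ShapeError("tail and body epoch stacks must have equal shape")
    n, nbins = te.shape
    if n < 3:
        raise ParameterError("correlogram needs at least 3 epochs")
    if mode == "across_trials":
        zt, okt = _standardize(te)
        zb, okb = _standardize(be)
        C = zt.T @ zb / (n - 1)
        C[~okt, :] = np.nan
        C[:, ~okb] = np.nan
    else:
        def ztime(mat):
            mu = mat.mean(axis=1, keepdims=True)
            sd = mat.std(axis=1, ddof=1, keepdims=True)
            sd[sd == 0] = np.nan
            return (mat - mu) / sd
        zt, zb = ztime(te), ztime(be)
        C = np.einsum("ei,ej->ij", zt, zb) / n
        C = np.clip(C, -1.0, 1.0)
    return CrossCorrelogram(C, n_trials=n, bin_times=tail_epochs.bin_times,
                            mode=mode)


def _largest_component(mask: np.ndarray, values: np.ndarray) -> ExtremeRegion | None:
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    labels, nlab = ndimage.label(mask, structure=structure)
    if nlab == 0:
        return None
    best_cells, best_mean = None, 0.0
    for lab in range(1, nlab + 1):
        cells = np.argwhere(labels == lab)
        mean = float(values[labels == lab].mean())
        if (best_cells is None or len(cells) > len(best_cells)
                or (len(cells) == len(best_cells)
                    and abs(mean) > abs(best_mean))):
            best_cells, best_mean = cells, mean
    return ExtremeRegion("", frozenset(map(tuple, best_cells)), best_mean)


def find_extreme_regions(C: CrossCorrelogram, pct: float = 5.0,
                         ) -> tuple[ExtremeRegion | None, ExtremeRegion | None]:
    """Hotspot and coldspot: the largest 8-connected component of cells in
    the upper (100 - pct)th / lower pct-th percentile tail of all defined
    cells (ties broken by larger absolute mean correlation)."""
    if not 0.0 < pct < 50.0:
        raise ParameterError("pct must lie strictly between 0 and 50")
    vals = C.matrix
    defined = np.isfinite(vals)
    if not defined.any():
        return None, None
    pool = vals[defined]
    hi = np.percentile(pool, 100.0 - pct)
    lo = np.percentile(pool, pct)
    hot = _largest_component(defined & (vals >= hi), vals)
    cold = _largest_component(defined & (vals <= lo), vals)
    if hot is not None:
        hot = ExtremeRegion("hotspot", hot.cells, hot.mean_value)
    if cold is not None:
        cold = ExtremeRegion("coldspot", cold.cells, cold.mean_value)
    return hot, cold


def correlogram_diagonal(C: CrossCorrelogram) -> tuple[np.ndarray, np.ndarray]:
    """Zero-lag coupling through the step cycle: (bin_times, C[i, i])."""
    return C.bin_times, np.diagonal(C.matrix).copy()
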