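"""Nucleosome repeat length estimation.

The phasogram counts start-to-start distances between fragments; its
periodic peaks sit at multiples of the repeat length, so the NRL is the
slope of peak position regressed on peak index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import linregress

from .fragments import FragmentSet
from .io import PathLike, xopen


@dataclass(frozen=True)
class Phasogram:
    """Frequency of start-to-start distances ``d`` in ``[1, delta]``.

    ``counts[i]`` is the number of ordered fragment pairs at distance
    ``i + 1`` bp.
    """

    delta: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if counts.shape != (self.delta,):
            raise ValueError("counts must have length delta")
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def distances(self) -> np.ndarray:
        return np.arange(1, self.delta + 1, dtype=np.int64)

    def count(self, distance: int) -> int:
        if not 1 <= distance <= self.delta:
            raise ValueError(f"distance {distance} outside [1, {self.delta}]")
        return int(self.counts[distance - 1])

    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "Phasogram") -> "Phasogram":
        if self.delta != other.delta:
            raise ValueError("cannot add phasograms with different delta")
        return Phasogram(self.delta, self.counts + other.counts)


@dataclass(frozen=True)
class NrlFit:
    """Linear fit of peak position vs peak index; the slope is the NRL."""

    peak_positions: tuple[int, ...]
    slope: float
    slope_err: float
    intercept: float
    r_squared: float


def compute_phasogram(frags: FragmentSet, delta: int) -> Phasogram:
    """Count ordered fragment pairs by start-to-start distance.

    For every pair ``(i, j)`` with ``start_j > start_i`` and
    ``start_j - start_i <= delta`` the count at that distance is
    incremented; equal starts (distance 0) are excluded.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    counts = np.zeros(delta + 1, dtype=np.int64)
    if len(frags) >= 2:
        starts = np.sort(frags.starts)
        n = starts.size
        hi = np.searchsorted(starts, starts + delta, side="right")
        lo = np.searchsorted(starts, starts, side="right")  # skip co-starting fragments
        m = hi - lo
        cum = np.concatenate([[0], np.cumsum(m)])
        total = int(cum[-1])
        if total:
            i = np.repeat(np.arange(n), m)
            j = np.arange(total) - np.repeat(cum[:-1], m) + np.repeat(lo, m)
            d = starts[j] - starts[i]
            counts = np.bincount(d, minlength=delta + 1).astype(np.int64)
    return Phasogram(delta, counts[1:])


def detect_peaks(
    phasogram: Phasogram,
    smooth_window: int = 51,
    polyorder: int = 3,
    min_separation: int = 100,
    exclude_below: int = 100,
    prominence: float | None = None,
) -> np.ndarray:
    """Peak positions (bp) of the Savitzky-Golay-smoothed phasogram.

    Local maxima separated by at least ``min_separation`` bp are kept;
    peaks below ``exclude_below`` bp are discarded (they stem from
    overlapping/duplicate fragments, not adjacent nucleosomes). If
    ``prominence`` is None, 1% of the smoothed dynamic range is used.
    """
    y = phasogram.counts.astype(np.float64)
    if y.size == 0 or not y.any():
        raise ValueError("phasogram is empty")
    if smooth_window >= y.size:
        raise ValueError("smoothing window must be smaller than the phasogram length")
    smoothed = savgol_filter(y, smooth_window, polyorder)
    if prominence is None:
        span = float(smoothed.max() - smoothed.min())
        prominence = 0.01 * span if span > 0 else None
    idx, _ = find_peaks(smoothed, distance=min_separation, prominence=prominence)
    positions = idx + 1  # counts[i] holds distance i + 1
    positions = positions[positions >= exclude_below]
    if positions.size < 2:
        raise ValueError(
            "fewer than two phasogram peaks detected; increase --delta or provide more fragments"
        )
    return positions


def fit_nrl(peak_positions) -> NrlFit:
    """Ordinary least squares of peak position vs peak index (1-based).

    With exactly two peaks the slope is the two-point difference and the
    slope error is reported as NaN (not determinable).
    """
    positions = np.asarray(peak_positions, dtype=np.float64)
    k = positions.size
    if k < 2:
        raise ValueError("at least two peaks are required to fit the NRL")
    index = np.arange(1, k + 1, dtype=np.float64)
    if k == 2:
        slope = float(positions[1] - positions[0])
        intercept = float(positions[0] - slope)
        slope_err = math.nan
        r_squared = 1.0
    else:
        res = linregress(index, positions)
        slope = float(res.slope)
        intercept = float(res.intercept)
        slope_err = float(res.stderr)
        r_squared = float(res.rvalue) ** 2
    if slope <= 0:
        raise ValueError(f"non-positive fitted repeat length ({slope:.2f} bp)")
    return NrlFit(tuple(int(p) for p in positions), slope, slope_err, intercept, r_squared)


def write_phasogram(phasogram: Phasogram, path: PathLike) -> None:
    """Two-column TSV: distance, count."""
    with xopen(path, "wt") as fh:
        for d, c in zip(phasogram.distances, phasogram.counts):
            fh.write(f"{d}\t{c}\n")


def read_phasogram(path: PathLike) -> Phasogram:
    distances, counts = [], []
    with xopen(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            d, c = line.split("\t")[:2]
            distances.append(int(d))
            counts.append(int(c))
    if not distances:
        raise ValueError(f"empty phasogram file: {path}")
    delta = max(distances)
    arr = np.zeros(delta, dtype=np.int64)
    arr[np.asarray(distances) - 1] = counts
    return Phasogram(delta, arr)
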