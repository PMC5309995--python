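"""Windowed occupancy tracks: fragment coverage, depth normalization,
region extraction, methylation-call conversion, and ``.occ`` file I/O.

An occupancy track holds one value per genomic window; the value is the
mean per-bp fragment coverage across the window's bases. ``.occ`` files are
two tab-separated columns (window start, value).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .fragments import FragmentSet
from .io import PathLike, xopen

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationParams:
    """Depth-normalization parameters.

    ``nuc_size`` is the average fragment size, ``n_reads`` the number of
    fragments in the input, and ``chr_length`` the mappable chromosome span.
    """

    nuc_size: float
    n_reads: int
    chr_length: int

    def __post_init__(self) -> None:
        if self.nuc_size <= 0 or self.n_reads <= 0 or self.chr_length <= 0:
            raise ValueError("all normalization parameters must be strictly positive")

    @property
    def expected_depth(self) -> float:
        return self.nuc_size * self.n_reads / self.chr_length


@dataclass(frozen=True)
class OccupancyTrack:
    """Per-window signal values for one chromosome."""

    chrom: str
    window_size: int
    starts: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "values", values)
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if starts.shape != values.shape or starts.ndim != 1:
            raise ValueError("starts and values must be 1-D arrays of equal length")
        if starts.size:
            if np.any(starts % self.window_size):
                raise ValueError("window starts must be multiples of window_size")
            if np.any(np.diff(starts) <= 0):
                raise ValueError("window starts must be strictly increasing")
            if np.any(values < 0):
                raise ValueError("occupancy values must be non-negative")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def end(self) -> int:
        """Exclusive end of the track domain (last window end; 0 if empty)."""
        return int(self.starts[-1]) + self.window_size if len(self) else 0

    def lookup(self, query_starts) -> np.ndarray:
        """Values at the given window starts.

        Positions inside the track domain ``[0, end)`` but absent from
        ``starts`` (zero-suppressed windows) return 0; positions outside the
        domain return NaN.
        """
        q = np.asarray(query_starts, dtype=np.int64)
        if not len(self):
            return np.full(q.shape, np.nan)
        out = np.zeros(q.shape, dtype=np.float64)
        idx = np.searchsorted(self.starts, q)
        hit = (idx < len(self)) & (self.starts[np.minimum(idx, len(self) - 1)] == q)
        out[hit] = self.values[idx[hit]]
        out[(q < 0) | (q >= self.end)] = np.nan
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OccupancyTrack):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.window_size == other.window_size
            and self.normalized == other.normalized
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.values, other.values)
        )


def compute_windowed_occupancy(
    frags: FragmentSet, window_size: int, keep_zeros: bool = True
) -> OccupancyTrack:
    """Convert fragments to a windowed occupancy track.

    Per-bp occupancy is the number of fragments covering the base; each
    window value is the mean per-bp occupancy over ``window_size`` bases
    (the trailing window is zero-padded beyond the last fragment end, i.e.
    always divided by ``window_size``).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not len(frags):
        log.warning("compute_windowed_occupancy: empty fragment set on %s", frags.chrom)
        return OccupancyTrack(frags.chrom, window_size, np.empty(0, np.int64), np.empty(0))
    span_end = frags.span_end
    n_win = math.ceil(span_end / window_size)
    L = n_win * window_size
    delta = np.bincount(frags.starts, minlength=L + 1).astype(np.int64)
    delta -= np.bincount(frags.ends, minlength=L + 1)
    cov = np.cumsum(delta[:L])
    values = cov.reshape(n_win, window_size).mean(axis=1)
    starts = np.arange(n_win, dtype=np.int64) * window_size
    if not keep_zeros:
        nz = values > 0
        starts, values = starts[nz], values[nz]
    return OccupancyTrack(frags.chrom, window_size, starts, values)


def normalize_occupancy(track: OccupancyTrack, params: NormalizationParams) -> OccupancyTrack:
    """Divide every raw window value by the expected sequencing depth
    ``nuc_size * n_reads / chr_length``."""
    if track.normalized:
        raise ValueError("track is already normalized")
    return replace(track, values=track.values / params.expected_depth, normalized=True)


def chromosome_span(frags: FragmentSet) -> int:
    """Mappable chromosome length: max fragment end minus min fragment start."""
    if not len(frags):
        raise ValueError("cannot compute chromosome span of an empty FragmentSet")
    return frags.span_end - frags.span_start


def extract_region(track: OccupancyTrack, from_bp: int, to_bp: int) -> OccupancyTrack:
    """Windows whose start lies in ``[from_bp, to_bp)``, values unchanged."""
    if from_bp >= to_bp:
        raise ValueError("interval must satisfy from < to")
    keep = (track.starts >= from_bp) & (track.starts < to_bp)
    if not keep.any():
        log.warning(
            "extract_region: no windows of %s in [%d, %d)", track.chrom, from_bp, to_bp
        )
    return replace(track, starts=track.starts[keep], values=track.values[keep])


def methylation_to_track(
    chrom: str,
    positions,
    fractions,
    threshold: float,
    window_size: int,
    keep_zeros: bool = True,
) -> tuple[OccupancyTrack, int]:
    """Windowed density of methylated cytosines.

    Cytosines with methylation fraction >= ``threshold`` count as 1-bp unit
    events at their position; window values are events per bp as in
    :func:`compute_windowed_occupancy`. Records with a fraction outside
    [0, 1] are rejected (counted, warned).
    """
    positions = np.asarray(positions, dtype=np.int64)
    fractions = np.asarray(fractions, dtype=np.float64)
    if positions.shape != fractions.shape:
        raise ValueError("positions and fractions must have equal length")
    valid = (fractions >= 0.0) & (fractions <= 1.0)
    n_rejected = int((~valid).sum())
    if n_rejected:
        log.warning("methylation_to_track: rejected %d records with fraction outside [0, 1]", n_rejected)
    positions, fractions = positions[valid], fractions[valid]
    if positions.size == 0:
        return OccupancyTrack(chrom, window_size, np.empty(0, np.int64), np.empty(0)), n_rejected
    events = positions[fractions >= threshold]
    # The track spans all observed cytosines, not only those passing the
    # threshold, so "no window" and "zero window" stay distinguishable.
    n_win = math.ceil((int(positions.max()) + 1) / window_size)
    L = n_win * window_size
    cov = np.bincount(events, minlength=L)[:L]
    values = cov.reshape(n_win, window_size).mean(axis=1)
    starts = np.arange(n_win, dtype=np.int64) * window_size
    if not keep_zeros:
        nz = values > 0
        starts, values = starts[nz], values[nz]
    return OccupancyTrack(chrom, window_size, starts, values), n_rejected


# ---------------------------------------------------------------------------
# .occ file I/O
# ---------------------------------------------------------------------------


def write_occ(track: OccupancyTrack, path: PathLike, keep_zeros: bool = True, decimals: int = 4) -> int:
    """Write a two-column (window start, value) occupancy file."""
    n = 0
    with xopen(path, "wt") as fh:
        for s, v in zip(track.starts, track.values):
            if not keep_zeros and v == 0:
                continue
            fh.write(f"{s}\t{v:.{decimals}f}\n")
            n += 1
    return n


def infer_window_size(starts: np.ndarray) -> int:
    """Window size as the GCD of the observed window starts."""
    starts = np.asarray(starts, dtype=np.int64)
    if starts.size < 2:
        raise ValueError("cannot infer window size from fewer than two windows; pass it explicitly")
    g = int(np.gcd.reduce(np.diff(starts)))
    first = int(starts[0])
    if first:
        g = math.gcd(g, first)
    return g


def read_occ(
    path: PathLike, chrom: str, window_size: int | None = None, normalized: bool = False
) -> OccupancyTrack:
    """Read a two-column occupancy file; infers the window size if omitted."""
    starts, values = [], []
    with xopen(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            starts.append(int(a))
            values.append(float(b))
    starts_arr = np.asarray(starts, dtype=np.int64)
    if window_size is None:
        window_size = infer_window_size(starts_arr)
    return OccupancyTrack(chrom, window_size, starts_arr, np.asarray(values), normalized=normalized)
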