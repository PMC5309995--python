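"""Feature-aligned occupancy matrices and aggregate (meta-)profiles.

Rows of a :class:`ProfileMatrix` are genomic features aligned at their
anchor (interval centre); columns are relative positions on the window
grid ``[-flank, +flank]``. Gaps (positions outside the available track) are
NaN and every downstream statistic is gap-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .io import PathLike, xopen
from .occupancy import OccupancyTrack

log = logging.getLogger(__name__)

_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class Feature:
    """A genomic feature with an alignment anchor at its interval centre."""

    chrom: str
    start: int
    end: int
    id: str
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad feature interval [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def anchor(self) -> int:
        return (self.start + self.end) // 2


class FeatureSet:
    """Ordered collection of features with unique ids."""

    def __init__(self, features: Sequence[Feature]) -> None:
        self.features = list(features)
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")
        self._by_id = {f.id: f for f in self.features}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __getitem__(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def scores(self) -> dict[str, float]:
        out = {}
        for f in self.features:
            if f.score is not None:
                out[f.id] = f.score
        return out


def read_features(path: PathLike) -> FeatureSet:
    """Read features from BED3+ (name column 4, score column 5, strand 6).

    Features without a name get a positional id ``chrom:start-end``.
    """
    features = []
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected at least 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else f"{chrom}:{start}-{end}"
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) >= 6 and fields[5] in _STRANDS else "."
            features.append(Feature(chrom, start, end, name, strand, score))
    return FeatureSet(features)


def write_features(features: Iterable[Feature], path: PathLike) -> int:
    n = 0
    with xopen(path, "wt") as fh:
        for f in features:
            score = 0 if f.score is None else f.score
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t{score:g}\t{f.strand}\n")
            n += 1
    return n


@dataclass(frozen=True)
class ProfileMatrix:
    """features x relative-position matrix of occupancy (NaN = gap)."""

    row_ids: tuple[str, ...]
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "row_ids", tuple(self.row_ids))
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.row_ids), positions.size):
            raise ValueError("values shape must be (n_rows, n_positions)")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row ids must be unique")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(row_id)]

    def subset(self, row_ids: Sequence[str]) -> "ProfileMatrix":
        index = {r: i for i, r in enumerate(self.row_ids)}
        rows = [index[r] for r in row_ids]
        return ProfileMatrix(tuple(row_ids), self.positions, self.values[rows])


def build_profile_matrix(
    tracks: Mapping[str, OccupancyTrack] | Sequence[OccupancyTrack],
    features: FeatureSet,
    flank: int,
) -> tuple[ProfileMatrix, int]:
    """Align per-chromosome tracks on feature anchors.

    ``flank`` must be a multiple of the window size; the position grid is
    ``-flank, ..., 0, ..., +flank``. Minus-strand rows are reversed so that
    positive positions are downstream of the feature. Features on
    chromosomes absent from ``tracks`` are dropped (the count is returned).
    """
    if not isinstance(tracks, Mapping):
        tracks = {t.chrom: t for t in tracks}
    if not tracks:
        raise ValueError("no occupancy tracks supplied")
    windows = {t.window_size for t in tracks.values()}
    if len(windows) != 1:
        raise ValueError(f"tracks have inconsistent window sizes: {sorted(windows)}")
    window = windows.pop()
    if flank % window:
        raise ValueError("flank must be a multiple of the window size")
    offsets = np.arange(-flank, flank + window, window, dtype=np.int64)
    rows, row_ids = [], []
    n_dropped = 0
    for f in features:
        track = tracks.get(f.chrom)
        if track is None:
            n_dropped += 1
            continue
        anchor_window = (f.anchor // window) * window
        row = track.lookup(anchor_window + offsets)
        if f.strand == "-":
            row = row[::-1]
        rows.append(row)
        row_ids.append(f.id)
    if n_dropped:
        log.warning("build_profile_matrix: dropped %d features on chromosomes without tracks", n_dropped)
    if not rows:
        raise ValueError("no features could be aligned to the supplied tracks")
    return ProfileMatrix(tuple(row_ids), offsets, np.vstack(rows)), n_dropped


def filter_artifacts(matrix: ProfileMatrix, max_fold: float = 10.0) -> tuple[ProfileMatrix, list[str]]:
    """Drop rows with suspiciously high occupancy (sequencing artifacts).

    A row is removed when its maximum exceeds ``max_fold`` times the median
    of all finite matrix values. The median is computed once on the
    pre-filter matrix (single pass), so the operation is deterministic and
    idempotent.
    """
    if max_fold <= 1:
        raise ValueError("max_fold must be > 1")
    finite = matrix.values[np.isfinite(matrix.values)]
    if finite.size == 0:
        raise ValueError("matrix has no finite values")
    median = float(np.median(finite))
    with np.errstate(invalid="ignore"):
        row_max = np.nanmax(np.where(np.isfinite(matrix.values), matrix.values, -np.inf), axis=1)
    keep = row_max <= max_fold * median
    removed = [r for r, k in zip(matrix.row_ids, keep) if not k]
    if not keep.any():
        raise ValueError("artifact filter removed every row; raise max_fold")
    if removed:
        log.info("filter_artifacts: removed %d rows exceeding %.3g x median", len(removed), max_fold)
    kept_ids = tuple(r for r, k in zip(matrix.row_ids, keep) if k)
    return ProfileMatrix(kept_ids, matrix.positions, matrix.values[keep]), removed


def aggregate_profile(matrix: ProfileMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gap-aware per-position mean.

    Returns ``(positions, mean, n)`` where ``n`` is the number of non-gap
    rows contributing to each position (mean is NaN where ``n`` is 0).
    """
    if matrix.n_rows < 1:
        raise ValueError("matrix must have at least one row")
    finite = np.isfinite(matrix.values)
    n = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        total = np.where(finite, matrix.values, 0.0).sum(axis=0)
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return matrix.positions.copy(), mean, n


def smooth_profile(profile, window: int = 51, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing; the window must be odd, larger than the
    polynomial order and smaller than the profile length."""
    values = np.asarray(profile, dtype=np.float64)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window <= polyorder:
        raise ValueError("smoothing window must exceed the polynomial order")
    if window >= values.size:
        raise ValueError("smoothing window must be smaller than the profile length")
    return savgol_filter(values, window, polyorder)


def derivative_profile(profile, step: float = 1.0) -> np.ndarray:
    """First derivative per bp: central differences inside, one-sided at the
    ends."""
    values = np.asarray(profile, dtype=np.float64)
    if values.size < 2:
        raise ValueError("at least two points are required")
    return np.gradient(values, step)


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------


def write_matrix(matrix: ProfileMatrix, path: PathLike) -> None:
    """TSV with an ``id`` column and one column per relative position."""
    with xopen(path, "wt") as fh:
        fh.write("id\t" + "\t".join(str(p) for p in matrix.positions) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            fh.write(rid + "\t" + "\t".join("nan" if not np.isfinite(v) else f"{v:.6g}" for v in row) + "\n")


def read_matrix(path: PathLike) -> ProfileMatrix:
    with xopen(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        positions = np.asarray([int(p) for p in header[1:]], dtype=np.int64)
        row_ids, rows = [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0]:
                continue
            row_ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    if not rows:
        raise ValueError(f"empty profile matrix file: {path}")
    return ProfileMatrix(tuple(row_ids), positions, np.asarray(rows))


def write_aggregate(positions, mean, n, path: PathLike) -> None:
    """Three-column TSV: position, mean, n."""
    with xopen(path, "wt") as fh:
        fh.write("position\tmean\tn\n")
        for p, m, k in zip(positions, mean, n):
            fh.write(f"{p}\t{'nan' if not np.isfinite(m) else format(m, '.6g')}\t{k}\n")
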