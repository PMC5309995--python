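"""Replicate averaging and stable/fuzzy region calling.

Region statistics are kept as a pandas DataFrame with columns
``chrom, start, end, mean_occ, abs_err, rel_err`` (one row per window);
:func:`classify_regions` appends a ``label`` column.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PathLike
from .occupancy import OccupancyTrack

log = logging.getLogger(__name__)

STABLE = "stable"
FUZZY = "fuzzy"
NEITHER = "neither"

REGION_COLUMNS = ["chrom", "start", "end", "mean_occ", "abs_err", "rel_err"]


def stack_tracks(tracks: Sequence[OccupancyTrack]) -> tuple[np.ndarray, np.ndarray]:
    """Positionally align replicate tracks on a common window grid.

    Returns ``(window_starts, matrix)`` where ``matrix`` is replicates x
    windows; windows missing from a replicate (zero-suppressed or beyond its
    span) are imputed as 0, since absence in an ``.occ`` file means no
    coverage.
    """
    if len(tracks) < 2:
        raise ValueError("at least two replicate tracks are required")
    window = tracks[0].window_size
    chrom = tracks[0].chrom
    for t in tracks[1:]:
        if t.window_size != window:
            raise ValueError(f"mismatched window sizes: {window} vs {t.window_size}")
        if t.chrom != chrom:
            raise ValueError(f"mismatched chromosomes: {chrom} vs {t.chrom}")
    grid_end = max(t.end for t in tracks)
    starts = np.arange(0, grid_end, window, dtype=np.int64)
    matrix = np.zeros((len(tracks), starts.size))
    for i, t in enumerate(tracks):
        row = t.lookup(starts)
        matrix[i] = np.nan_to_num(row, nan=0.0)
    return starts, matrix


def average_replicates(tracks: Sequence[OccupancyTrack], error: str = "se") -> pd.DataFrame:
    """Per-window replicate mean and variability.

    ``abs_err`` is the standard error ``sd / sqrt(n)`` (sample SD, n-1
    denominator) when ``error='se'``, or the sample SD when ``error='sd'``.
    ``rel_err`` is ``abs_err / mean_occ`` (NaN where the mean is 0).
    """
    if error not in ("se", "sd"):
        raise ValueError("error must be 'se' or 'sd'")
    starts, matrix = stack_tracks(tracks)
    n = matrix.shape[0]
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    abs_err = sd / np.sqrt(n) if error == "se" else sd
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_err = np.where(mean > 0, abs_err / mean, np.nan)
    window = tracks[0].window_size
    return pd.DataFrame(
        {
            "chrom": tracks[0].chrom,
            "start": starts,
            "end": starts + window,
            "mean_occ": mean,
            "abs_err": abs_err,
            "rel_err": rel_err,
        }
    )


def mean_track(tracks: Sequence[OccupancyTrack], error: str = "se") -> OccupancyTrack:
    """Replicate-averaged occupancy as a track (for ``.occ`` export)."""
    stats = average_replicates(tracks, error=error)
    return OccupancyTrack(
        tracks[0].chrom,
        tracks[0].window_size,
        stats["start"].to_numpy(),
        stats["mean_occ"].to_numpy(),
        normalized=all(t.normalized for t in tracks),
    )


def classify_regions(
    stats: pd.DataFrame,
    stable_max: float = 0.2,
    fuzzy_min: float = 2.0,
    min_occ: float = 0.0,
) -> pd.DataFrame:
    """Label windows stable/fuzzy/neither by relative error.

    A window is *stable* iff ``rel_err < stable_max`` and
    ``mean_occ >= min_occ``; *fuzzy* iff ``rel_err > fuzzy_min`` (strict
    comparisons on both sides). Windows with zero mean occupancy have an
    undefined relative error and are skipped (dropped from the output).
    """
    if stable_max >= fuzzy_min:
        raise ValueError("stable_max must be smaller than fuzzy_min")
    called = stats[stats["mean_occ"] > 0].copy()
    rel = called["rel_err"].to_numpy()
    occ = called["mean_occ"].to_numpy()
    label = np.full(len(called), NEITHER, dtype=object)
    label[(rel < stable_max) & (occ >= min_occ)] = STABLE
    label[rel > fuzzy_min] = FUZZY
    called["label"] = label
    return called


def write_region_stats(stats: pd.DataFrame, path: PathLike) -> None:
    """Write region statistics (and label, if present) as BED-like TSV."""
    stats.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_region_stats(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"region stats file {path} lacks columns {missing}")
    return df
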