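"""Differential occupancy between two conditions.

The relative change of a window is ``o_diff = 2 (o1 - o2) / (o1 + o2)``,
bounded in [-2, 2]; windows whose |o_diff| reaches the threshold are
reported as gained (o_diff > 0) or lost (o_diff < 0), condition 1 relative
to condition 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GAINED = "gained"
LOST = "lost"

_SIGNAL_COLUMNS = {"occupancy": "mean_occ", "rel_err": "rel_err"}


def relative_change(occ_1, occ_2):
    """``2 (occ_1 - occ_2) / (occ_1 + occ_2)``; NaN where both are zero.

    Accepts scalars or arrays (element-wise).
    """
    o1 = np.asarray(occ_1, dtype=np.float64)
    o2 = np.asarray(occ_2, dtype=np.float64)
    if np.any(o1 < 0) or np.any(o2 < 0):
        raise ValueError("occupancies must be non-negative")
    total = o1 + o2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, 2.0 * (o1 - o2) / total, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def compare_conditions(
    stats_1: pd.DataFrame,
    stats_2: pd.DataFrame,
    signal: str = "occupancy",
    threshold: float = 0.99,
) -> pd.DataFrame:
    """Windows whose signal changed by at least ``threshold`` (|o_diff|).

    The two region-statistics streams are aligned positionally by
    ``(chrom, start)``; windows present in only one stream count as 0 in the
    other. Windows where both signals are zero are skipped. The threshold is
    inclusive. Returns a DataFrame with columns
    ``chrom, start, end, occ_1, occ_2, o_diff, direction``.
    """
    if signal not in _SIGNAL_COLUMNS:
        raise ValueError(f"signal must be one of {sorted(_SIGNAL_COLUMNS)}")
    col = _SIGNAL_COLUMNS[signal]
    for name, df in (("stats_1", stats_1), ("stats_2", stats_2)):
        if col not in df.columns:
            raise ValueError(f"{name} lacks column {col!r}")
    w1 = _window_size(stats_1)
    w2 = _window_size(stats_2)
    if w1 is not None and w2 is not None and w1 != w2:
        raise ValueError(f"mismatched window sizes: {w1} vs {w2}")
    window = w1 or w2
    a = stats_1[["chrom", "start", col]].rename(columns={col: "occ_1"})
    b = stats_2[["chrom", "start", col]].rename(columns={col: "occ_2"})
    merged = a.merge(b, on=["chrom", "start"], how="outer").fillna({"occ_1": 0.0, "occ_2": 0.0})
    merged = merged.dropna(subset=["occ_1", "occ_2"])  # NaN signal (e.g. undefined rel_err)
    merged = merged.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    merged = merged[(merged["occ_1"] > 0) | (merged["occ_2"] > 0)]
    o_diff = relative_change(merged["occ_1"].to_numpy(), merged["occ_2"].to_numpy())
    merged = merged.assign(o_diff=o_diff)
    hits = merged[np.abs(merged["o_diff"]) >= threshold].copy()
    hits["direction"] = np.where(hits["o_diff"] > 0, GAINED, LOST)
    hits["end"] = hits["start"] + (window if window else 0)
    return hits[["chrom", "start", "end", "occ_1", "occ_2", "o_diff", "direction"]].reset_index(
        drop=True
    )


def _window_size(stats: pd.DataFrame) -> int | None:
    if "end" not in stats.columns or not len(stats):
        return None
    widths = np.unique(stats["end"].to_numpy() - stats["start"].to_numpy())
    if widths.size != 1:
        raise ValueError("region stats contain windows of unequal size")
    return int(widths[0])
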