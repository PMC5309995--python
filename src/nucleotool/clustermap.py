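"""Row ordering, k-means clustering and visualization of profile matrices,
including transferring a saved order between experimental conditions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .aggregate import Feature, FeatureSet, ProfileMatrix, write_features
from .io import PathLike, xopen

log = logging.getLogger(__name__)

SORT_MEAN = "mean_signal"
SORT_SCORE = "external_score"


@dataclass(frozen=True)
class RowOrder:
    """An ordering of matrix rows, optionally with cluster labels.

    ``labels[i]`` (1-based cluster number) belongs to ``ids[i]``.
    ``provenance`` records how the order was produced (mode, subregion, k,
    seed) so it can be persisted next to the order itself.
    """

    ids: tuple[str, ...]
    labels: tuple[int, ...] | None = None
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        if self.labels is not None:
            labels = tuple(int(x) for x in self.labels)
            if len(labels) != len(self.ids):
                raise ValueError("labels must align with ids")
            if labels and min(labels) < 1:
                raise ValueError("cluster labels are 1-based")
            object.__setattr__(self, "labels", labels)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("order ids must be unique")

    def to_tsv(self, path: PathLike) -> None:
        with xopen(path, "wt") as fh:
            fh.write("id\trank\tcluster\n")
            for rank, rid in enumerate(self.ids, 1):
                cluster = "" if self.labels is None else str(self.labels[rank - 1])
                fh.write(f"{rid}\t{rank}\t{cluster}\n")

    @classmethod
    def from_tsv(cls, path: PathLike) -> "RowOrder":
        ids, labels = [], []
        with xopen(path) as fh:
            header = fh.readline()
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if not fields or not fields[0]:
                    continue
                ids.append(fields[0])
                labels.append(int(fields[2]) if len(fields) > 2 and fields[2] else None)
        has_labels = all(l is not None for l in labels) and bool(labels)
        return cls(tuple(ids), tuple(labels) if has_labels else None)


def _subregion_columns(matrix: ProfileMatrix, subregion: tuple[int, int] | None) -> np.ndarray:
    if subregion is None:
        return np.ones(matrix.positions.size, dtype=bool)
    a, b = subregion
    if a > b:
        raise ValueError("subregion must satisfy a <= b")
    if a < matrix.positions.min() or b > matrix.positions.max():
        raise ValueError(
            f"subregion [{a}, {b}] outside matrix positions "
            f"[{matrix.positions.min()}, {matrix.positions.max()}]"
        )
    mask = (matrix.positions >= a) & (matrix.positions <= b)
    if not mask.any():
        raise ValueError("subregion selects no matrix columns")
    return mask


def sort_rows(
    matrix: ProfileMatrix,
    mode: str = SORT_MEAN,
    subregion: tuple[int, int] | None = None,
    scores: Mapping[str, float] | None = None,
) -> RowOrder:
    """Order rows by descending key: mean signal over ``subregion``
    (``mean_signal``) or an external per-id score (``external_score``).
    Ties keep the original row order (stable sort)."""
    if mode == SORT_MEAN:
        cols = _subregion_columns(matrix, subregion)
        with np.errstate(invalid="ignore"):
            key = np.nanmean(matrix.values[:, cols], axis=1)
        key = np.nan_to_num(key, nan=-np.inf)
    elif mode == SORT_SCORE:
        if scores is None:
            raise ValueError("external_score sorting requires scores")
        missing = [r for r in matrix.row_ids if r not in scores]
        if missing:
            raise ValueError(f"missing scores for rows: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        key = np.asarray([scores[r] for r in matrix.row_ids], dtype=np.float64)
    else:
        raise ValueError(f"unknown sort mode {mode!r}")
    order = np.argsort(-key, kind="stable")
    return RowOrder(
        tuple(matrix.row_ids[i] for i in order),
        provenance={"mode": mode, "subregion": subregion},
    )


def kmeans_rows(
    matrix: ProfileMatrix,
    k: int,
    subregion: tuple[int, int] | None = None,
    seed: int = 0,
    row_norm: bool = False,
) -> RowOrder:
    """K-means clustering of rows on the subregion columns.

    Euclidean distance with k-means++ initialization and a fixed seed, so
    results are reproducible. Rows with gaps inside the subregion are
    dropped with a warning. Clusters are displayed in order of descending
    mean signal, rows within a cluster sorted by descending row mean.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cols = _subregion_columns(matrix, subregion)
    X_all = matrix.values[:, cols]
    usable = np.isfinite(X_all).all(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.warning("kmeans_rows: dropped %d rows with gaps in the subregion", n_dropped)
    X = X_all[usable]
    usable_ids = [r for r, u in zip(matrix.row_ids, usable) if u]
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} usable rows")
    if row_norm:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw_labels = km.fit_predict(X)
    row_means = X_all[usable].mean(axis=1)
    cluster_means = np.asarray([row_means[raw_labels == c].mean() for c in range(k)])
    display_rank = {c: rank + 1 for rank, c in enumerate(np.argsort(-cluster_means))}
    ordered_ids: list[str] = []
    ordered_labels: list[int] = []
    for cluster in sorted(display_rank, key=display_rank.get):
        members = np.flatnonzero(raw_labels == cluster)
        members = members[np.argsort(-row_means[members], kind="stable")]
        for m in members:
            ordered_ids.append(usable_ids[m])
            ordered_labels.append(display_rank[cluster])
    return RowOrder(
        tuple(ordered_ids),
        tuple(ordered_labels),
        provenance={"mode": "kmeans", "subregion": subregion, "k": k, "seed": seed, "row_norm": row_norm},
    )


def apply_order(matrix: ProfileMatrix, order: RowOrder) -> tuple[ProfileMatrix, int]:
    """Rearrange a (second-condition) matrix to a saved row order by id.

    Order ids absent from the matrix are skipped; the skipped count is
    returned. An empty intersection is an error.
    """
    present = set(matrix.row_ids)
    kept = [rid for rid in order.ids if rid in present]
    n_missing = len(order.ids) - len(kept)
    if not kept:
        raise ValueError("no ids of the saved order are present in the matrix")
    if n_missing:
        log.warning("apply_order: %d order ids absent from the matrix", n_missing)
    return matrix.subset(kept), n_missing


def export_clusters(
    order: RowOrder, features: FeatureSet, out_dir: PathLike, prefix: str = "cluster"
) -> dict[int, Path]:
    """Write one BED file per cluster with the original feature coordinates.

    Every labelled id must resolve in ``features``; offenders are reported
    in the error message.
    """
    if order.labels is None:
        raise ValueError("order has no cluster labels")
    unresolvable = [rid for rid in order.ids if rid not in features]
    if unresolvable:
        raise ValueError(f"ids not found in the feature set: {unresolvable}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_cluster: dict[int, list[Feature]] = {}
    for rid, label in zip(order.ids, order.labels):
        by_cluster.setdefault(label, []).append(features[rid])
    paths: dict[int, Path] = {}
    for label in sorted(by_cluster):
        path = out_dir / f"{prefix}_{label}.bed"
        write_features(by_cluster[label], path)
        paths[label] = path
    return paths


def plot_heatmap(
    matrix: ProfileMatrix,
    path: PathLike,
    clip_percentile: float = 98.0,
    cmap: str = "viridis",
    title: str | None = None,
) -> None:
    """Render the matrix as a heatmap with the colour scale clipped at an
    upper percentile so single artifacts cannot flatten the palette."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = matrix.values[np.isfinite(matrix.values)]
    vmax = float(np.percentile(finite, clip_percentile)) if finite.size else 1.0
    fig, ax = plt.subplots(figsize=(6, 8))
    extent = (float(matrix.positions[0]), float(matrix.positions[-1]), matrix.n_rows, 0)
    im = ax.imshow(matrix.values, aspect="auto", cmap=cmap, vmin=0, vmax=vmax, extent=extent, interpolation="nearest")
    ax.set_xlabel("position relative to anchor (bp)")
    ax.set_ylabel("features")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="occupancy")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
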