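"""Mapped-read preprocessing: BED I/O, strand extension, mate merging,
chromosome splitting and single-end fragment-length estimation.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io import PathLike, xopen

log = logging.getLogger(__name__)

PLUS = "+"
MINUS = "-"
UNKNOWN = "."

_STRANDS = frozenset({PLUS, MINUS, UNKNOWN})


@dataclass(frozen=True)
class Fragment:
    """One sequenced DNA fragment (or raw read) as a genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {sorted(_STRANDS)}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentSet:
    """All fragments of a single chromosome, stored as flat arrays.

    Parameters
    ----------
    chrom
        Chromosome name shared by every fragment.
    starts, ends
        Integer arrays of 0-based half-open interval bounds.
    strands
        Optional array of ``+``/``-``/``.`` per fragment; defaults to unknown.
    """

    def __init__(self, chrom: str, starts, ends, strands=None) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.shape != ends.shape or starts.ndim != 1:
            raise ValueError("starts and ends must be 1-D arrays of equal length")
        if starts.size and starts.min() < 0:
            raise ValueError("negative fragment start")
        if np.any(ends <= starts):
            raise ValueError("every fragment must satisfy end > start")
        if strands is None:
            strands = np.full(starts.shape, UNKNOWN, dtype="U1")
        else:
            strands = np.asarray(strands, dtype="U1")
            if strands.shape != starts.shape:
                raise ValueError("strands length mismatch")
            if starts.size and not set(np.unique(strands)) <= _STRANDS:
                raise ValueError("invalid strand value")
        self.chrom = chrom
        self.starts = starts
        self.ends = ends
        self.strands = strands

    @classmethod
    def from_fragments(cls, fragments: Sequence[Fragment], chrom: str | None = None) -> "FragmentSet":
        fragments = list(fragments)
        if chrom is None:
            if not fragments:
                raise ValueError("chrom required for an empty FragmentSet")
            chrom = fragments[0].chrom
        if any(f.chrom != chrom for f in fragments):
            raise ValueError("all fragments must share one chromosome")
        return cls(
            chrom,
            [f.start for f in fragments],
            [f.end for f in fragments],
            [f.strand for f in fragments],
        )

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def count(self) -> int:
        return len(self)

    @property
    def span_start(self) -> int:
        if not len(self):
            raise ValueError("empty FragmentSet has no span")
        return int(self.starts.min())

    @property
    def span_end(self) -> int:
        if not len(self):
            raise ValueError("empty FragmentSet has no span")
        return int(self.ends.max())

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def __iter__(self) -> Iterator[Fragment]:
        for s, e, st in zip(self.starts, self.ends, self.strands):
            yield Fragment(self.chrom, int(s), int(e), str(st))

    def sorted_by_start(self) -> "FragmentSet":
        order = np.argsort(self.starts, kind="stable")
        return FragmentSet(self.chrom, self.starts[order], self.ends[order], self.strands[order])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
            and np.array_equal(self.strands, other.strands)
        )


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def _parse_bed_line(line: str, lineno: int) -> Fragment | None:
    line = line.rstrip("\n")
    if not line.strip() or line.startswith(_SKIP_PREFIXES):
        return None
    fields = line.split("\t")
    if len(fields) < 3:
        fields = line.split()
    if len(fields) < 3:
        raise ValueError(f"line {lineno}: expected at least 3 BED columns, got {line!r}")
    strand = fields[5] if len(fields) >= 6 and fields[5] in _STRANDS else UNKNOWN
    return Fragment(fields[0], int(fields[1]), int(fields[2]), strand)


def read_bed(path: PathLike) -> list[Fragment]:
    """Read a BED3+ file (plain or gzipped) into a record list."""
    records = []
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, 1):
            frag = _parse_bed_line(line, lineno)
            if frag is not None:
                records.append(frag)
    return records


def read_fragmentsets(path: PathLike) -> dict[str, FragmentSet]:
    """Read a BED file and group records per chromosome (order preserved)."""
    by_chrom: dict[str, list[Fragment]] = {}
    for frag in read_bed(path):
        by_chrom.setdefault(frag.chrom, []).append(frag)
    return {c: FragmentSet.from_fragments(frags, c) for c, frags in by_chrom.items()}


def write_bed(path: PathLike, fragments: Iterable[Fragment]) -> int:
    """Write fragments as BED6 (name ``.``, score 0); returns record count."""
    n = 0
    with xopen(path, "wt") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t.\t0\t{f.strand}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtendReport:
    n_extended: int
    n_rejected: int
    n_clamped: int


def extend_single_end(reads: FragmentSet, fragment_length: int) -> tuple[FragmentSet, ExtendReport]:
    """Extend single-end reads to full fragments in a strand-specific way.

    Plus-strand ``[s, e)`` becomes ``[s, s + L)``; minus-strand becomes
    ``[e - L, e)`` clamped at the chromosome origin. Reads of unknown strand
    are rejected (counted and logged), so the output count equals the input
    count minus the rejects.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    known = reads.strands != UNKNOWN
    n_rejected = int((~known).sum())
    if n_rejected:
        log.warning("extend_single_end: rejected %d reads with unknown strand", n_rejected)
    starts = reads.starts[known]
    ends = reads.ends[known]
    strands = reads.strands[known]
    plus = strands == PLUS
    new_starts = np.where(plus, starts, ends - fragment_length)
    new_ends = np.where(plus, starts + fragment_length, ends)
    n_clamped = int((new_starts < 0).sum())
    if n_clamped:
        log.warning("extend_single_end: clamped %d fragments at position 0", n_clamped)
    new_starts = np.maximum(new_starts, 0)
    out = FragmentSet(reads.chrom, new_starts, new_ends, strands)
    return out, ExtendReport(len(out), n_rejected, n_clamped)


def merge_paired_end(records: Sequence[Fragment]) -> tuple[list[Fragment], int]:
    """Merge consecutive mate records into one fragment per pair.

    Each output fragment spans ``min(starts)`` to ``max(ends)`` of the mate
    pair. Mate pairs on different chromosomes are skipped with a warning;
    an odd number of records is an error naming the dangling record.

    Returns ``(fragments, n_skipped_pairs)``.
    """
    if len(records) % 2:
        dangling = records[-1]
        raise ValueError(
            f"odd number of records ({len(records)}); dangling mate "
            f"{dangling.chrom}:{dangling.start}-{dangling.end}"
        )
    out: list[Fragment] = []
    n_skipped = 0
    for a, b in zip(records[::2], records[1::2]):
        if a.chrom != b.chrom:
            log.warning(
                "merge_paired_end: skipping cross-chromosome pair %s:%d-%d / %s:%d-%d",
                a.chrom, a.start, a.end, b.chrom, b.start, b.end,
            )
            n_skipped += 1
            continue
        out.append(Fragment(a.chrom, min(a.start, b.start), max(a.end, b.end)))
    return out, n_skipped


def estimate_fragment_length(reads: FragmentSet, max_shift: int = 400) -> int:
    """Estimate the average fragment length of single-end reads.

    Uses strand cross-correlation: the per-bp density of plus-strand read
    starts is correlated (Pearson) against the density of minus-strand read
    end coordinates shifted by ``d``; the estimate is the shift in
    ``[1, max_shift]`` maximizing the correlation.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    plus_starts = reads.starts[reads.strands == PLUS]
    minus_ends = reads.ends[reads.strands == MINUS]
    if plus_starts.size == 0 or minus_ends.size == 0:
        raise ValueError("reads on both strands are required to estimate fragment length")
    lo = int(min(plus_starts.min(), minus_ends.min()))
    hi = int(max(plus_starts.max(), minus_ends.max())) + 1
    T = hi - lo
    p = np.bincount(plus_starts - lo, minlength=T).astype(np.float64)
    m = np.bincount(minus_ends - lo, minlength=T).astype(np.float64)
    p_mean = p.mean()
    p_var = np.mean(p * p) - p_mean**2
    if p_var <= 0:
        raise ValueError("degenerate plus-strand density")
    # Suffix sums let each shifted slice's mean/variance come cheap.
    s1 = np.concatenate([np.cumsum(m[::-1])[::-1], [0.0]])
    s2 = np.concatenate([np.cumsum((m * m)[::-1])[::-1], [0.0]])
    best_d, best_r = 0, -np.inf
    for d in range(1, min(max_shift, T - 1) + 1):
        mb = s1[d] / T
        vb = s2[d] / T - mb * mb
        if vb <= 0:
            continue
        xc = p[: T - d] @ m[d:]
        r = (xc / T - p_mean * mb) / np.sqrt(p_var * vb)
        if r > best_r:
            best_d, best_r = d, r
    if best_d == 0:
        raise ValueError("no informative shift found; increase max_shift or provide more reads")
    return best_d


def split_by_chromosome(
    in_path: PathLike, out_dir: PathLike, gzip_out: bool = False
) -> dict[str, tuple[Path, int]]:
    """Split a mixed-chromosome BED file into one file per chromosome.

    Input lines are copied verbatim (original order preserved within each
    chromosome). Returns ``{chrom: (path, record_count)}``.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise NotADirectoryError(f"output directory does not exist: {out_dir}")
    lines_by_chrom: dict[str, list[str]] = {}
    with xopen(in_path) as fh:
        for lineno, line in enumerate(fh, 1):
            frag = _parse_bed_line(line, lineno)
            if frag is None:
                continue
            lines_by_chrom.setdefault(frag.chrom, []).append(line.rstrip("\n"))
    if not lines_by_chrom:
        log.warning("split_by_chromosome: no records in %s", in_path)
        return {}
    suffix = ".bed.gz" if gzip_out else ".bed"
    result: dict[str, tuple[Path, int]] = {}
    for chrom, lines in lines_by_chrom.items():
        path = out_dir / f"{chrom}{suffix}"
        with xopen(path, "wt") as fh:
            fh.write("\n".join(lines) + "\n")
        result[chrom] = (path, len(lines))
    return result
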