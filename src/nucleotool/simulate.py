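"""Synthetic fragment data with known ground truth.

Two generators cover the test surface of the whole package:

* :func:`simulate_array_reads` places regularly spaced nucleosome arrays
  (known repeat length, jitter, sampling depth) and emits MNase-like
  fragments, for phasogram / repeat-length recovery.
* :func:`simulate_replicates` plants stable, fuzzy (zero-inflated,
  high-variance), gained and lost regions across replicate fragment sets of
  two conditions, for stability classification and differential recovery.

All randomness flows through one ``numpy`` generator seeded from the model,
so outputs are reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import MINUS, PLUS, FragmentSet

STABLE = "stable"
FUZZY = "fuzzy"
BACKGROUND = "background"
GAINED = "gained"
LOST = "lost"


@dataclass(frozen=True)
class ArrayModel:
    """Parameters of a regular nucleosome-array fragment generator."""

    chrom: str = "chrS"
    chrom_length: int = 200_000
    nrl_true: int = 190
    jitter_sd: float = 20.0
    frag_len: int = 147
    frag_len_sd: float = 0.0
    depth: int = 1
    occupancy_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrl_true < 1 or self.frag_len < 1 or self.depth < 1:
            raise ValueError("nrl_true, frag_len and depth must be positive")
        if not 0.0 <= self.occupancy_prob <= 1.0:
            raise ValueError("occupancy_prob must be in [0, 1]")
        if self.chrom_length <= 2 * self.frag_len:
            raise ValueError("chrom_length too small for the fragment length")


def simulate_array_reads(model: ArrayModel) -> FragmentSet:
    """Fragments sampled from a regularly spaced nucleosome array.

    Dyads sit at ``margin + i * nrl_true + N(0, jitter_sd)``; each dyad is
    kept with ``occupancy_prob`` and contributes ``depth`` fragments of
    length ``N(frag_len, frag_len_sd)`` centred on the dyad, with random
    strand. Fragment starts are clamped at 0.
    """
    rng = np.random.default_rng(model.seed)
    margin = model.frag_len
    grid = np.arange(margin, model.chrom_length - margin, model.nrl_true, dtype=np.float64)
    dyads = grid + rng.normal(0.0, model.jitter_sd, size=grid.size)
    keep = rng.random(grid.size) < model.occupancy_prob
    dyads = dyads[keep]
    dyads = np.repeat(dyads, model.depth)
    if model.frag_len_sd > 0:
        lens = np.rint(rng.normal(model.frag_len, model.frag_len_sd, size=dyads.size)).astype(np.int64)
        lens = np.maximum(lens, 1)
    else:
        lens = np.full(dyads.size, model.frag_len, dtype=np.int64)
    starts = np.rint(dyads).astype(np.int64) - lens // 2
    starts = np.maximum(starts, 0)
    ends = starts + lens
    strands = np.where(rng.random(dyads.size) < 0.5, PLUS, MINUS)
    order = np.argsort(starts, kind="stable")
    return FragmentSet(model.chrom, starts[order], ends[order], strands[order])


def reads_from_fragments(frags: FragmentSet, read_len: int = 36) -> FragmentSet:
    """Truncate fragments to 5'-anchored single-end reads (test helper)."""
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    plus = frags.strands == PLUS
    starts = np.where(plus, frags.starts, np.maximum(frags.ends - read_len, 0))
    ends = np.where(plus, np.minimum(frags.starts + read_len, frags.ends), frags.ends)
    return FragmentSet(frags.chrom, starts, ends, frags.strands)


@dataclass(frozen=True)
class ScenarioSpec:
    """Planted-effect layout for replicate simulation.

    Region lists hold half-open ``(start, end)`` intervals; any part of the
    chromosome not covered by an effect region is background. Effect
    parameters: stable regions draw a per-replicate depth multiplier with
    CV ``stable_cv``; background with CV ``background_cv``; fuzzy regions
    are zero-inflated (probability ``fuzzy_p`` of producing any fragments,
    boosted by ``fuzzy_boost`` when they do); gained (lost) regions multiply
    the condition-1 (condition-2) depth by ``fold_change`` on top of a
    low-CV multiplier with CV ``diff_cv``.
    """

    stable_regions: tuple[tuple[int, int], ...] = ()
    fuzzy_regions: tuple[tuple[int, int], ...] = ()
    gained_regions: tuple[tuple[int, int], ...] = ()
    lost_regions: tuple[tuple[int, int], ...] = ()
    n_replicates: int = 5
    base_rate: float = 0.6
    stable_cv: float = 0.05
    background_cv: float = 0.5
    fuzzy_p: float = 0.2
    fuzzy_boost: float = 1.5
    fold_change: float = 4.0
    diff_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("at least two replicates per condition")
        if self.base_rate <= 0 or self.fold_change <= 0:
            raise ValueError("base_rate and fold_change must be positive")
        if not 0.0 <= self.fuzzy_p <= 1.0:
            raise ValueError("fuzzy_p must be in [0, 1]")

    def regions(self, chrom_length: int) -> list[tuple[int, int, str]]:
        """Labelled, disjoint regions covering ``[0, chrom_length)``."""
        labelled = (
            [(s, e, STABLE) for s, e in self.stable_regions]
            + [(s, e, FUZZY) for s, e in self.fuzzy_regions]
            + [(s, e, GAINED) for s, e in self.gained_regions]
            + [(s, e, LOST) for s, e in self.lost_regions]
        )
        labelled.sort()
        cursor = 0
        out: list[tuple[int, int, str]] = []
        for s, e, lab in labelled:
            if s < cursor:
                raise ValueError(f"overlapping or out-of-order effect regions at {s}")
            if e > chrom_length:
                raise ValueError(f"region [{s}, {e}) exceeds chromosome length {chrom_length}")
            if s > cursor:
                out.append((cursor, s, BACKGROUND))
            out.append((s, e, lab))
            cursor = e
        if cursor < chrom_length:
            out.append((cursor, chrom_length, BACKGROUND))
        return out

    @classmethod
    def default(cls, chrom_length: int = 200_000, block: int = 2000, **kwargs) -> "ScenarioSpec":
        """Alternating stable / background / fuzzy / background blocks."""
        stable, fuzzy = [], []
        pos, phase = 0, 0
        while pos + block <= chrom_length:
            if phase == 0:
                stable.append((pos, pos + block))
            elif phase == 2:
                fuzzy.append((pos, pos + block))
            pos += block
            phase = (phase + 1) % 4
        return cls(stable_regions=tuple(stable), fuzzy_regions=tuple(fuzzy), **kwargs)

    @classmethod
    def default_differential(cls, chrom_length: int = 200_000, block: int = 2000, **kwargs) -> "ScenarioSpec":
        """Gained and lost blocks embedded in low-variance surroundings."""
        gained, lost, stable = [], [], []
        pos, phase = 0, 0
        while pos + block <= chrom_length:
            if phase == 0:
                stable.append((pos, pos + block))
            elif phase == 2:
                gained.append((pos, pos + block))
            elif phase == 4:
                stable.append((pos, pos + block))
            elif phase == 6:
                lost.append((pos, pos + block))
            pos += block
            phase = (phase + 1) % 8
        return cls(
            stable_regions=tuple(stable),
            gained_regions=tuple(gained),
            lost_regions=tuple(lost),
            **kwargs,
        )

    @classmethod
    def null(cls, **kwargs) -> "ScenarioSpec":
        """No planted effects: the whole chromosome is background."""
        return cls(**kwargs)


@dataclass(frozen=True)
class SimulatedScenario:
    """Replicate fragment sets for two conditions plus the planted truth."""

    cond1: tuple[FragmentSet, ...]
    cond2: tuple[FragmentSet, ...]
    truth: pd.DataFrame  # columns: start, end, label

    def truth_windows(self, window_size: int, margin: int = 200) -> pd.DataFrame:
        """Window-level truth labels, restricted to windows at least
        ``margin`` bp inside their region (coverage ramps at region edges
        would otherwise blur the planted classes)."""
        rows = []
        for start, end, label in self.truth.itertuples(index=False):
            lo = math.ceil((start + margin) / window_size) * window_size
            hi = end - margin - window_size
            for w in range(lo, hi + 1, window_size):
                rows.append((w, label))
        return pd.DataFrame(rows, columns=["start", "label"])


def _multiplier(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    s2 = math.log1p(cv * cv)
    return float(rng.lognormal(-s2 / 2.0, math.sqrt(s2)))


def simulate_replicates(model: ArrayModel, scenario: ScenarioSpec) -> SimulatedScenario:
    """Generate per-replicate, per-condition fragment sets with planted
    stable/fuzzy/gained/lost regions (see :class:`ScenarioSpec`).

    Fragments are confined to their region (uniform starts over
    ``[start, end - frag_len]``, fixed length), so planted zero-coverage
    windows stay exactly zero.
    """
    rng = np.random.default_rng(model.seed)
    regions = scenario.regions(model.chrom_length)
    frag_len = model.frag_len

    def one_replicate(cond: int) -> FragmentSet:
        starts_parts = []
        for start, end, label in regions:
            span = end - start - frag_len
            if span <= 0:
                continue
            if label == STABLE:
                mult = _multiplier(rng, scenario.stable_cv)
            elif label == BACKGROUND:
                mult = _multiplier(rng, scenario.background_cv)
            elif label == FUZZY:
                fired = rng.random() < scenario.fuzzy_p
                mult = scenario.fuzzy_boost * _multiplier(rng, scenario.background_cv) if fired else 0.0
            elif label == GAINED:
                mult = _multiplier(rng, scenario.diff_cv) * (scenario.fold_change if cond == 1 else 1.0)
            elif label == LOST:
                mult = _multiplier(rng, scenario.diff_cv) * (scenario.fold_change if cond == 2 else 1.0)
            else:  # pragma: no cover
                raise AssertionError(label)
            if mult <= 0:
                continue
            n = rng.poisson(scenario.base_rate * mult * span)
            if n:
                starts_parts.append(start + rng.integers(0, span + 1, size=n))
        if starts_parts:
            starts = np.sort(np.concatenate(starts_parts))
        else:
            starts = np.empty(0, dtype=np.int64)
        return FragmentSet(model.chrom, starts, starts + frag_len)

    cond1 = tuple(one_replicate(1) for _ in range(scenario.n_replicates))
    cond2 = tuple(one_replicate(2) for _ in range(scenario.n_replicates))
    truth = pd.DataFrame(regions, columns=["start", "end", "label"])
    return SimulatedScenario(cond1, cond2, truth)
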