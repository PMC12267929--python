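"""Alignment- and genome-level diversity statistics and sliding-window tracks.

Gap and ambiguity handling is pairwise deletion throughout: a column enters
a pairwise comparison only when both sequences carry an unambiguous base.
All statistics are invariant under row reordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .seqio import Alignment, GenomeRecord, encode

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class WindowTrack:
    """Values on a sliding (or tiling) window over columns/positions."""

    window: int
    step: int
    starts: np.ndarray       # anchored 0-based start positions
    values: np.ndarray
    partial_last: bool = False  # a trailing partial window was appended

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.values):
            raise ConfigurationError("starts and values must align")

    def to_frame(self, length: int | None = None) -> pd.DataFrame:
        ends = self.starts + self.window
        if length is not None:
            ends = np.minimum(ends, length)
        return pd.DataFrame(
            {
                "window_start_1based": self.starts + 1,
                "window_end": ends,
                "value": self.values,
            }
        )


def expected_window_count(length: int, window: int, step: int) -> int:
    """floor((L - window)/step) + 1 for L >= window, else 0."""
    if length < window:
        return 0
    return (length - window) // step + 1


def _base_mask(matrix: np.ndarray) -> np.ndarray:
    return np.isin(matrix, _ACGT)


def variable_sites(alignment: Alignment) -> int:
    """Columns with >= 2 distinct unambiguous bases (gaps/ambiguity ignored)."""
    m = alignment.matrix
    if m.shape[0] < 2:
        raise ConfigurationError("need >= 2 sequences")
    ok = _base_mask(m)
    n_var = 0
    for base_counts in _column_base_counts(m, ok).T:
        if (base_counts > 0).sum() >= 2:
            n_var += 1
    return n_var


def parsimony_informative_sites(alignment: Alignment) -> int:
    """Columns with >= 2 distinct bases each occurring in >= 2 sequences."""
    m = alignment.matrix
    if m.shape[0] < 2:
        raise ConfigurationError("need >= 2 sequences")
    ok = _base_mask(m)
    n_pi = 0
    for base_counts in _column_base_counts(m, ok).T:
        if (base_counts >= 2).sum() >= 2:
            n_pi += 1
    return n_pi


def _column_base_counts(m: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """(4, L) counts of A, C, G, T per column, ignoring non-bases."""
    counts = np.zeros((4, m.shape[1]), dtype=np.int64)
    for i, b in enumerate(_ACGT):
        counts[i] = ((m == b) & ok).sum(axis=0)
    return counts


def pairwise_identity(alignment: Alignment) -> float:
    """Mean over unordered pairs of percent identical compared columns.

    A compared column has unambiguous bases in both rows.  Pairs with zero
    compared columns are excluded from the mean with a warning.
    """
    m = alignment.matrix
    n = m.shape[0]
    if n < 2:
        raise ConfigurationError("need >= 2 sequences")
    ok = _base_mask(m)
    vals = []
    for i, j in combinations(range(n), 2):
        both = ok[i] & ok[j]
        total = int(both.sum())
        if total == 0:
            warnings.warn(
                f"pair ({alignment.sample_ids[i]}, {alignment.sample_ids[j]}) "
                "has no compared columns; excluded from identity mean"
            )
            continue
        same = int(((m[i] == m[j]) & both).sum())
        vals.append(100.0 * same / total)
    if not vals:
        raise ConfigurationError("no pair with compared columns")
    return float(np.mean(vals))


def gc_content(seq_or_alignment) -> float:
    """Percent (G+C)/(A+C+G+T); gaps, N and ambiguity codes excluded."""
    if isinstance(seq_or_alignment, Alignment):
        m = seq_or_alignment.matrix.ravel()
    elif isinstance(seq_or_alignment, GenomeRecord):
        m = encode(seq_or_alignment.sequence)
    else:
        m = encode(str(seq_or_alignment))
    bases = int(np.isin(m, _ACGT).sum())
    if bases == 0:
        return float("nan")
    gc = int(np.isin(m, np.frombuffer(b"GC", dtype=np.uint8)).sum())
    return 100.0 * gc / bases


def _pair_diff_comp(m: np.ndarray, ok: np.ndarray, i: int, j: int,
                    cols: slice | None = None):
    oki = ok[i] if cols is None else ok[i, cols]
    okj = ok[j] if cols is None else ok[j, cols]
    mi = m[i] if cols is None else m[i, cols]
    mj = m[j] if cols is None else m[j, cols]
    both = oki & okj
    comp = int(both.sum())
    diff = int(((mi != mj) & both).sum())
    return diff, comp


def pi(alignment: Alignment) -> float:
    """Nucleotide diversity: mean over unordered pairs of
    differences / compared sites (pairwise deletion)."""
    m = alignment.matrix
    n = m.shape[0]
    if n < 2:
        raise ConfigurationError("need >= 2 sequences")
    ok = _base_mask(m)
    vals = []
    for i, j in combinations(range(n), 2):
        diff, comp = _pair_diff_comp(m, ok, i, j)
        if comp:
            vals.append(diff / comp)
    return float(np.mean(vals)) if vals else float("nan")


def pi_windows(alignment: Alignment, window: int = 600, step: int = 100) -> WindowTrack:
    """Sliding-window nucleotide diversity on alignment columns.

    Windows with no compared sites in any pair get NaN.
    """
    L = alignment.length
    m = alignment.matrix
    ok = _base_mask(m)
    n = m.shape[0]
    starts = np.arange(0, expected_window_count(L, window, step)) * step
    values = np.empty(len(starts))
    pairs = list(combinations(range(n), 2))
    for w, s in enumerate(starts):
        cols = slice(int(s), int(s) + window)
        vals = []
        for i, j in pairs:
            diff, comp = _pair_diff_comp(m, ok, i, j, cols)
            if comp:
                vals.append(diff / comp)
        values[w] = np.mean(vals) if vals else np.nan
    return WindowTrack(window, step, starts, values)


def mdc_density(
    sites: Sequence, length: int, window: int = 1000
) -> WindowTrack:
    """MDC counts on a non-overlapping tiling (step = window).

    ``sites`` are MdcSite objects or integer columns.  When the length is
    not divisible by the window, the trailing partial window is counted and
    flagged, so counts always sum to the total site count.
    """
    positions = np.array(
        [s if isinstance(s, (int, np.integer)) else s.column for s in sites],
        dtype=int,
    )
    if positions.size and (positions.min() < 0 or positions.max() >= length):
        raise ConfigurationError("site positions outside [0, length)")
    n_full = length // window
    partial = length % window != 0
    starts = np.arange(0, (n_full + (1 if partial else 0))) * window
    values = np.zeros(len(starts), dtype=int)
    if positions.size:
        idx = positions // window
        np.add.at(values, idx, 1)
    return WindowTrack(window, window, starts, values, partial_last=partial)


def gc_windows(
    genome: GenomeRecord | str, window: int = 100, step: int | None = None
) -> WindowTrack:
    """Percent GC per window over a genome sequence (default: tiling)."""
    seq = genome.sequence if isinstance(genome, GenomeRecord) else str(genome)
    arr = encode(seq)
    if step is None:
        step = window
    L = arr.size
    starts = np.arange(0, expected_window_count(L, window, step)) * step
    isbase = np.isin(arr, _ACGT)
    isgc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8))
    values = np.empty(len(starts))
    for w, s in enumerate(starts):
        sl = slice(int(s), int(s) + window)
        nb = int(isbase[sl].sum())
        values[w] = 100.0 * int(isgc[sl].sum()) / nb if nb else np.nan
    return WindowTrack(window, step, starts, values)


def divergent_block_scan(
    alignment: Alignment,
    focal_sample: str,
    min_run: int = 100,
    min_frac: float = 0.3,
) -> list[tuple[int, int]]:
    """Maximal column runs where the focal sample diverges from the column
    majority in at least ``min_frac`` of columns.

    The majority state is taken over the unambiguous bases of the other
    samples.  Maximal positive-scoring segments of the per-column score
    (divergent -> 1-min_frac, else -min_frac) are reported when they span at
    least ``min_run`` columns; this is equivalent to a run-fraction
    threshold with divergent columns at both ends.
    """
    focal_idx = alignment.sample_ids.index(focal_sample)
    m = alignment.matrix
    others = np.delete(np.arange(m.shape[0]), focal_idx)
    ok = _base_mask(m)
    counts = _column_base_counts(m[others], ok[others])
    majority = _ACGT[np.argmax(counts, axis=0)]
    has_majority = counts.sum(axis=0) > 0
    divergent = (m[focal_idx] != majority) & ok[focal_idx] & has_majority

    score = np.where(divergent, 1.0 - min_frac, -min_frac)
    # maximal positive-sum segments (simple left-to-right scan)
    blocks: list[tuple[int, int]] = []
    best_sum = cur = 0.0
    start = best_start = best_end = 0
    i = 0
    L = len(score)
    while i < L:
        if cur <= 0:
            cur = 0.0
            start = i
            best_sum = 0.0
            best_start = best_end = i
        cur += score[i]
        if cur > best_sum:
            best_sum = cur
            best_end = i + 1
            best_start = start
        if cur <= 0 or i == L - 1:
            if best_sum > 0 and best_end - best_start >= min_run:
                blocks.append((best_start, best_end))
            cur = 0.0
        i += 1
    # merge overlaps produced by restarts
    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
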