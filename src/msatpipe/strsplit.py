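"""Separate a simple tandem repeat from its flanking regions.

Amplicon inserts have the structure ``left_flank + motif*k + right_flank``.
Length-based genotyping needs the repeat region isolated from the flanks, so
this module locates the best-scoring tandem run in a sequence, scanning all
motif sizes from 2 to 6 bp.  Scoring follows the classic tandem-finder
convention: +1 for a base matching the periodic consensus of the run, -1 for
a mismatch, which tolerates occasional interruptions in the repeat.  Runs
are trimmed to whole motif copies; on score ties the run with more copies
(i.e. the primitive, shorter period) wins, then the longer and leftmost run.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

MIN_MOTIF = 2
MAX_MOTIF = 6

__all__ = ["SplitResult", "split_tandem_repeat", "MIN_MOTIF", "MAX_MOTIF"]


@dataclass(frozen=True)
class SplitResult:
    """Decomposition of a sequence into flank / tandem repeat / flank."""

    left_flank: str
    repeat_region: str
    right_flank: str
    motif: str
    score: int

    @property
    def found(self) -> bool:
        return bool(self.repeat_region)

    @property
    def repeat_length(self) -> int:
        return len(self.repeat_region)

    @property
    def n_copies(self) -> int:
        return len(self.repeat_region) // len(self.motif) if self.motif else 0


def _consensus_score(seq: str, start: int, stop: int, m: int) -> int:
    """Matches minus mismatches of seq[start:stop] against its own periodic
    consensus with period m (majority base per motif column)."""
    region = seq[start:stop]
    score = 0
    for j in range(m):
        col = region[j::m]
        if not col:
            continue
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        score += best - (len(col) - best)
    return score


def _best_window(eq: np.ndarray, min_len: int) -> tuple[int, int] | None:
    """Max-sum contiguous window of +-1 scores with length >= min_len.

    Sum ties prefer the shortest window (zero-net detours into flanking
    sequence are dropped), then the leftmost."""
    n = eq.size
    if n < min_len:
        return None
    score = np.where(eq, 1, -1)
    prefix = np.concatenate([[0], np.cumsum(score)])
    best = None
    best_key = None
    min_idx = 0
    for b in range(min_len, n + 1):
        a_limit = b - min_len
        # on equal prefix minima keep the later index -> shorter window
        if prefix[a_limit] <= prefix[min_idx]:
            min_idx = a_limit
        key = (int(prefix[b] - prefix[min_idx]), -(b - min_idx), -min_idx)
        if best_key is None or key > best_key:
            best_key = key
            best = (min_idx, b)
    return best


def _trim_to_copies(seq: str, start: int, stop: int, m: int) -> tuple[int, int, int] | None:
    """Trim a run to a whole number of motif copies, choosing the trim
    (from the left or the right) with the better consensus score."""
    excess = (stop - start) % m
    options = []
    for a, b in ((start + excess, stop), (start, stop - excess)) if excess else ((start, stop),):
        if b - a >= 2 * m:
            options.append((_consensus_score(seq, a, b, m), -a, a, b))
    if not options:
        return None
    score, _, a, b = max(options)
    return a, b, score


@lru_cache(maxsize=100_000)
def split_tandem_repeat(sequence: str) -> SplitResult:
    """Find the maximal-scoring tandem run and return flanks, repeat, motif.

    All motif sizes in [2, 6] and all offsets are scanned; the run must
    contain at least two whole motif copies.  When no such run exists the
    whole sequence is returned as ``left_flank`` with an empty repeat region
    (``found`` is False).
    """
    seq = sequence.upper()
    L = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    # key: (score, -mismatches, n_copies, region_len, -start, -motif_len)
    candidates: list[tuple[int, ...]] = []
    for m in range(MIN_MOTIF, min(MAX_MOTIF, L // 2) + 1):
        eq = arr[:-m] == arr[m:]
        win = _best_window(eq, m)
        if win is None:
            continue
        trimmed = _trim_to_copies(seq, win[0], win[1] + m, m)
        if trimmed is None:
            continue
        a, b, score = trimmed
        if score <= 0:
            continue
        # a genuine tandem must contain two exact adjacent motif copies:
        # m consecutive lag-m matches somewhere inside the run
        inner = eq[a : b - m]
        if not np.convolve(inner, np.ones(m, dtype=int), mode="valid").max(initial=0) >= m:
            continue
        mismatches = ((b - a) - score) // 2
        candidates.append((score, -mismatches, (b - a) // m, b - a, -a, -m, a, b))
    if not candidates:
        return SplitResult(seq, "", "", "", 0)
    best = max(candidates)
    a, b = best[6], best[7]
    m = -best[5]
    return SplitResult(seq[:a], seq[a:b], seq[b:], seq[a : a + m], score)
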