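"""Unit-cost edit-distance primitives used by the fuzzy matchers.

All matchers in this package reduce to two queries:

* global Levenshtein distance between two sequences, and
* the best approximate occurrence of a short pattern inside a longer
  text (semi-global alignment, free at both ends of the text).

Costs are unit: one per mismatch, insertion or deletion.  A
substitutions-only (Hamming) search is provided for callers that want
to forbid indels in short flank matches.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "levenshtein",
    "semiglobal_distance",
    "find_approx",
    "find_hamming",
    "Occurrence",
]


class Occurrence(NamedTuple):
    """An approximate occurrence of a pattern in a text."""

    start: int
    end: int  # half-open
    distance: int


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def levenshtein(a: str, b: str) -> int:
    """Global unit-cost Levenshtein distance between ``a`` and ``b``."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    bb = _encode(b)
    n = len(b)
    idx = np.arange(n + 1)
    prev = idx.astype(np.int64)
    for i, ch in enumerate(_encode(a)):
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = i + 1
        cur[1:] = np.minimum(prev[:-1] + (bb != ch), prev[1:] + 1)
        # propagate insertions left-to-right: cur[j] = min_k<=j cur[k] + (j-k)
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev[-1])


def semiglobal_distance(pattern: str, text: str) -> int:
    """Minimum edit distance between ``pattern`` and any substring of ``text``.

    The whole pattern must be consumed; the text is free at both ends.
    """
    if not pattern:
        return 0
    if not text:
        return len(pattern)
    tt = _encode(text)
    n = len(text)
    idx = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int64)
    for i, ch in enumerate(_encode(pattern)):
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = i + 1
        cur[1:] = np.minimum(prev[:-1] + (tt != ch), prev[1:] + 1)
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev.min())


def find_approx(pattern: str, text: str, max_edit: int) -> Optional[Occurrence]:
    """Best approximate occurrence of ``pattern`` in ``text``.

    Returns the occurrence minimising ``(distance, start, end)`` — lowest
    distance first, then leftmost start, then shortest extent — or ``None``
    if no occurrence has distance ≤ ``max_edit``.
    """
    m, n = len(pattern), len(text)
    if m == 0:
        return Occurrence(0, 0, 0)
    if n == 0:
        return Occurrence(0, 0, m) if m <= max_edit else None
    # vectorized distance-only pass first; the start-tracking DP below is
    # pure Python and only worth running when an occurrence exists
    if semiglobal_distance(pattern, text) > max_edit:
        return None
    # DP over (pattern row, text column) tracking, per cell, the minimal
    # distance and among equal distances the smallest start column.
    INF = m + n + 1
    prev_d = [0] * (n + 1)
    prev_s = list(range(n + 1))
    for i in range(1, m + 1):
        ci = pattern[i - 1]
        cur_d = [INF] * (n + 1)
        cur_s = [0] * (n + 1)
        cur_d[0] = i
        cur_s[0] = 0
        for j in range(1, n + 1):
            sub = prev_d[j - 1] + (0 if text[j - 1] == ci else 1)
            dele = prev_d[j] + 1
            ins = cur_d[j - 1] + 1
            best = min(sub, dele, ins)
            # smallest start among transitions achieving the best distance
            s = INF
            if sub == best:
                s = prev_s[j - 1]
            if dele == best:
                s = min(s, prev_s[j])
            if ins == best:
                s = min(s, cur_s[j - 1])
            cur_d[j] = best
            cur_s[j] = s
        prev_d, prev_s = cur_d, cur_s
    best_occ: Optional[Occurrence] = None
    for j in range(n + 1):
        d = prev_d[j]
        if d > max_edit:
            continue
        occ = Occurrence(prev_s[j], j, d)
        if best_occ is None or (d, occ.start, occ.end) < (
            best_occ.distance,
            best_occ.start,
            best_occ.end,
        ):
            best_occ = occ
    return best_occ


def find_hamming(pattern: str, text: str, max_mismatch: int) -> Optional[Occurrence]:
    """Best substitutions-only occurrence of ``pattern`` in ``text``.

    Sliding-window mismatch count; ties resolved as in :func:`find_approx`.
    """
    m, n = len(pattern), len(text)
    if m == 0:
        return Occurrence(0, 0, 0)
    if m > n:
        return None
    pp = _encode(pattern)
    tt = _encode(text)
    windows = np.lib.stride_tricks.sliding_window_view(tt, m)
    mism = (windows != pp).sum(axis=1)
    best = int(mism.min())
    if best > max_mismatch:
        return None
    start = int(np.argmin(mism))
    return Occurrence(start, start + m, best)
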