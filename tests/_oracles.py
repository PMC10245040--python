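"""Independent brute-force oracles used to validate the fuzzy matchers.

Deliberately naive implementations, kept separate from the package code
paths they check.
"""

from __future__ import annotations


def naive_levenshtein(a: str, b: str) -> int:
    """Textbook full-matrix Levenshtein, no vectorization."""
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
    return d[m][n]


def brute_best_occurrence(pattern: str, text: str):
    """Exhaustive best approximate occurrence over all substrings of ``text``.

    Returns (distance, start, end) minimizing that tuple, or None for an
    empty text with a non-empty pattern.
    """
    best = None
    for i in range(len(text) + 1):
        for j in range(i, len(text) + 1):
            d = naive_levenshtein(pattern, text[i:j])
            cand = (d, i, j)
            if best is None or cand < best:
                best = cand
    return best


def brute_semiglobal(pattern: str, text: str) -> int:
    """Min distance of the pattern against any substring of the text."""
    best = brute_best_occurrence(pattern, text)
    return best[0] if best else len(pattern)


def ols_normal_equations(x, y):
    """Straight-line least squares via the normal equations (no numpy.polyfit)."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    y_hat = [intercept + slope * v for v in x]
    ybar = sy / n
    ss_res = sum((a - b) ** 2 for a, b in zip(y, y_hat))
    ss_tot = sum((a - ybar) ** 2 for a in y)
    r2 = 1.0 - ss_res / ss_tot
    return slope, intercept, r2
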