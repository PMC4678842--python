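"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the aligner oracle
is a full O(nm) dynamic program with no seeding, windowing or banding;
the Fisher oracle enumerates hypergeometric tables in exact rational
arithmetic; the coverage oracle recounts depth base by base.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive infix (free target ends) edit-distance alignment

def _forward_pass(q: np.ndarray, t: np.ndarray) -> tuple[int, int]:
    """(best end position in t, edit distance) of aligning all of q to
    some infix of t, by full DP with unit costs."""
    n = len(t)
    idx = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int32)  # D[0][j] = 0: free start
    for i in range(1, len(q) + 1):
        sub = prev[:-1] + (t != q[i - 1])
        tmp = np.minimum(sub, prev[1:] + 1)  # diagonal vs consume-query
        vals = np.concatenate(([i], tmp))  # D[i][0] = i boundary
        # left-gap closure: D[i][j] = min_k<=j vals[k] + (j - k)
        prev = np.minimum.accumulate(vals - idx) + idx
    j = int(np.argmin(prev))
    return j, int(prev[j])


def locate_infix(query: str, target: str) -> tuple[int, int, int]:
    """(start, end, distance) of the best infix alignment of *query* in
    *target* (full dynamic programming, no heuristics)."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    end, dist = _forward_pass(q, t)
    back, dist2 = _forward_pass(q[::-1].copy(), t[:end][::-1].copy())
    assert dist2 == dist
    return end - back, end, dist


def global_counts(query: str, window: str) -> tuple[int, int]:
    """(matches, alignment columns) of an optimal global unit-cost
    alignment of *query* against *window*, via full matrix + traceback."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    m, n = len(q), len(w)
    idx = np.arange(n + 1)
    D = np.zeros((m + 1, n + 1), dtype=np.int32)
    D[0] = idx
    for i in range(1, m + 1):
        sub = D[i - 1, :-1] + (w != q[i - 1])
        tmp = np.minimum(sub, D[i - 1, 1:] + 1)
        vals = np.concatenate(([i], tmp))
        D[i] = np.minimum.accumulate(vals - idx) + idx
    i, j, matches, cols = m, n, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (q[i - 1] != w[j - 1]):
            matches += int(q[i - 1] == w[j - 1])
            i, j, cols = i - 1, j - 1, cols + 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            i, cols = i - 1, cols + 1
        else:
            j, cols = j - 1, cols + 1
    return matches, cols


def align_oracle(query: str, target: str) -> tuple[int, int, float]:
    """(start, end, identity) from the exhaustive aligner."""
    start, end, _ = locate_infix(query, target)
    matches, cols = global_counts(query, target[start:end])
    return start, end, matches / cols


# ---------------------------------------------------------------------------
# exact two-sided Fisher test by enumeration

def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric probabilities <= P(observed), computed in
    exact rational arithmetic (suitable for small tables)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = pmf(a)
    cutoff = p_obs * (Fraction(10**7 + 1, 10**7))  # tolerate fp ties
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(k)
        if p <= cutoff:
            total += p
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# naive coverage recount

def naive_depth(alignments, ref_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    depth = {name: np.zeros(L, dtype=np.int64) for name, L in ref_lengths.items()}
    for aln in alignments:
        for pos in range(aln.ref_interval.start, aln.ref_interval.end):
            if 0 <= pos < len(depth[aln.ref]):
                depth[aln.ref][pos] += 1
    return depth


def naive_window_means(depth: np.ndarray, size: int, step: int) -> list[tuple[int, int, float]]:
    """Window means by direct per-base summation, using the package's
    window-placement convention (full windows plus trailing partial)."""
    L = len(depth)
    starts = []
    s = 0
    while s + size <= L:
        starts.append(s)
        s += step
    if starts and starts[-1] + size < L and starts[-1] + step < L:
        starts.append(starts[-1] + step)
    if not starts:
        starts = [0]
    out = []
    for s in starts:
        e = min(s + size, L)
        total = 0
        for pos in range(s, e):
            total += int(depth[pos])
        out.append((s, e, total / (e - s)))
    return out
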