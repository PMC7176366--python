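"""Independent brute-force oracles used across the suite.

These deliberately share no code with the package's dynamic-programming
kernels or its statistics wrappers: alignment scores come from explicit
recursion over edit operations applied to every substring pair, and
Mann-Whitney p-values from complete enumeration of group assignments.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

from scipy.stats import rankdata

_M, _GA, _GB = 0, 1, 2  # last-operation states for affine gap accounting


def global_affine_score(a, b, score_of, gap_open, gap_extend, memo=True):
    """Best global alignment score by recursion over edit operations."""
    first = gap_open + gap_extend

    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, rec(i + 1, j + 1, _M) + score_of(a[i], b[j]))
        if i < len(a):
            cost = gap_extend if state == _GA else first
            best = max(best, rec(i + 1, j, _GA) - cost)
        if j < len(b):
            cost = gap_extend if state == _GB else first
            best = max(best, rec(i, j + 1, _GB) - cost)
        return best

    if memo:
        rec = lru_cache(maxsize=None)(rec)
    return rec(0, 0, _M)


def local_affine_score(a, b, score_of, gap_open, gap_extend, memo=True):
    """Best local score: exhaustive max over all substring pairs (and 0)."""
    best = 0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = global_affine_score(
                        a[i1:i2], b[j1:j2], score_of, gap_open, gap_extend, memo=memo
                    )
                    if s > best:
                        best = s
    return best


def mannwhitney_exact_p(x, y):
    """Two-sided exact p by enumerating all C(n1+n2, n1) group assignments.

    Tie-free input assumed.  The p-value is the null probability of a U
    at least as far from n1*n2/2 as the observed one.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y
    ranks = rankdata(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    u_min = min(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        total += 1
        u = sum(ranks[k] for k in comb) - n1 * (n1 + 1) / 2.0
        if min(u, n1 * n2 - u) <= u_min + 1e-9:
            count += 1
    return count / total
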