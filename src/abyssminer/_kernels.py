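"""Numba dynamic-programming kernels for protein alignment.

Conventions shared by every kernel:

* sequences are encoded as int8 index arrays (0..19 amino acids, 20 = X);
* the substitution matrix is a dense (21, 21) int64 array;
* an affine gap of length k costs ``gap_open + k * gap_extend`` (NCBI
  convention, so the first gapped residue costs open+extend);
* traceback ties are broken diagonal > up > left, where "up" consumes a
  query residue (gap in the target) and "left" consumes a target residue.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# pointer states
_STOP, _DIAG, _UP, _LEFT = 0, 1, 2, 3


@njit(cache=True)
def sw_score(q, t, S, gap_open, gap_extend):
    """Best local (Smith-Waterman) affine-gap score; score only."""
    m, n = q.shape[0], t.shape[0]
    H = np.zeros(n + 1, dtype=np.int64)
    E = np.full(n + 1, -(1 << 60), dtype=np.int64)
    best = 0
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        diag = H[0]
        H[0] = 0
        F = -(1 << 60)
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[j] = max(H[j] - first, E[j] - gap_extend)
            F = max(H[j - 1] - first, F - gap_extend)
            h = diag + S[qi, t[j - 1]]
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_align(q, t, S, gap_open, gap_extend):
    """Local alignment with traceback.

    Returns (score, q_start, q_end, t_start, t_end, matches, columns)
    with spans 0-based half-open on the input sequences.
    """
    m, n = q.shape[0], t.shape[0]
    NEG = -(1 << 60)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    first = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - first, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - first, F[i - 1, j] - gap_extend)
            E[i, j] = e
            F[i, j] = f
            d = H[i - 1, j - 1] + S[qi, t[j - 1]]
            # evaluate in reverse priority so ties resolve diag > up > left
            h = 0
            p = _STOP
            if e > 0 and e >= h:
                h = e
                p = _LEFT
            if f > 0 and f >= h:
                h = f
                p = _UP
            if d > 0 and d >= h:
                h = d
                p = _DIAG
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i, j = bi, bj
    matches = 0
    columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        p = ptr[i, j]
        if p == _DIAG:
            columns += 1
            if q[i - 1] == t[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif p == _UP:
            # consume query residue, gap in target; may span several rows
            columns += 1
            i -= 1
        elif p == _LEFT:
            columns += 1
            j -= 1
        else:
            break
    return best, i, bi, j, bj, matches, columns


@njit(cache=True)
def nw_score(q, t, S, gap_open, gap_extend):
    """Global (Needleman-Wunsch) affine-gap score, end gaps penalized."""
    m, n = q.shape[0], t.shape[0]
    NEG = -(1 << 60)
    first = gap_open + gap_extend
    H = np.empty(n + 1, dtype=np.int64)
    E = np.full(n + 1, NEG, dtype=np.int64)
    H[0] = 0
    for j in range(1, n + 1):
        H[j] = -(gap_open + j * gap_extend)
    for i in range(1, m + 1):
        diag = H[0]
        H[0] = -(gap_open + i * gap_extend)
        F = NEG
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[j] = max(H[j] - first, E[j] - gap_extend)
            F = max(H[j - 1] - first, F - gap_extend)
            h = diag + S[qi, t[j - 1]]
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            diag = H[j]
            H[j] = h
    return H[n]


@njit(cache=True)
def nw_align(q, t, S, gap_open, gap_extend):
    """Global alignment with traceback.

    Returns (score, ops) where ops is an int8 array over {1: diag,
    2: up/gap-in-target, 3: left/gap-in-query} read left to right.
    """
    m, n = q.shape[0], t.shape[0]
    NEG = -(1 << 60)
    first = gap_open + gap_extend
    H = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    H[0, 0] = 0
    for j in range(1, n + 1):
        E[0, j] = -(gap_open + j * gap_extend)
        H[0, j] = E[0, j]
        ptr[0, j] = _LEFT
    for i in range(1, m + 1):
        F[i, 0] = -(gap_open + i * gap_extend)
        H[i, 0] = F[i, 0]
        ptr[i, 0] = _UP
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - first, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - first, F[i - 1, j] - gap_extend)
            E[i, j] = e
            F[i, j] = f
            d = H[i - 1, j - 1] + S[qi, t[j - 1]]
            h = e
            p = _LEFT
            if f >= h:
                h = f
                p = _UP
            if d >= h:
                h = d
                p = _DIAG
            H[i, j] = h
            ptr[i, j] = p
    ops = np.empty(m + n, dtype=np.int8)
    k = m + n
    i, j = m, n
    while i > 0 or j > 0:
        p = ptr[i, j]
        k -= 1
        ops[k] = p
        if p == _DIAG:
            i -= 1
            j -= 1
        elif p == _UP:
            i -= 1
        else:
            j -= 1
    return H[m, n], ops[k:]


@njit(cache=True)
def profile_align(pa, pb, S, gap_open, gap_extend):
    """Profile-profile global alignment (sum-of-pairs expected score).

    ``pa``/``pb`` are (columns, 21) residue-frequency profiles (index 20
    is X; gap fraction is simply mass missing from the rows).  Column
    score is the expectation of the substitution score under the two
    frequency vectors.  Returns the op array as in :func:`nw_align`.
    """
    m, n = pa.shape[0], pb.shape[0]
    # precompute column-vs-column expected scores
    sa = pa @ S.astype(np.float64)  # (m, 21)
    cs = sa @ pb.T  # (m, n)
    NEG = -1.0e30
    first = float(gap_open + gap_extend)
    ext = float(gap_extend)
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -(first + (j - 1) * ext)
        H[0, j] = E[0, j]
        ptr[0, j] = _LEFT
    for i in range(1, m + 1):
        F[i, 0] = -(first + (i - 1) * ext)
        H[i, 0] = F[i, 0]
        ptr[i, 0] = _UP
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - first, E[i, j - 1] - ext)
            f = max(H[i - 1, j] - first, F[i - 1, j] - ext)
            E[i, j] = e
            F[i, j] = f
            d = H[i - 1, j - 1] + cs[i - 1, j - 1]
            h = e
            p = _LEFT
            if f >= h:
                h = f
                p = _UP
            if d >= h:
                h = d
                p = _DIAG
            H[i, j] = h
            ptr[i, j] = p
    ops = np.empty(m + n, dtype=np.int8)
    k = m + n
    i, j = m, n
    while i > 0 or j > 0:
        p = ptr[i, j]
        k -= 1
        ops[k] = p
        if p == _DIAG:
            i -= 1
            j -= 1
        elif p == _UP:
            i -= 1
        else:
            j -= 1
    return ops[k:]
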