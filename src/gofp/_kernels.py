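"""Numba dynamic-programming kernels for pairwise and profile alignment.

Three-state affine-gap DP (match / gap-in-B / gap-in-A).  A gap of length L
costs ``gap_open + L * gap_extend`` (both negative), the BLAST penalty
convention.  Tie-breaks are fixed: match state is preferred over a gap that
consumes the first sequence, which is preferred over a gap that consumes
the second; ties on the optimal cell keep the first cell in row-major scan
order, which makes every traceback deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30

# predecessor-state codes
_M, _X, _Y, _START = 0, 1, 2, 3


@njit(cache=False)
def nw_affine(a, b, sub, gap_open, gap_extend):
    """Global Needleman-Wunsch with affine gaps.

    Returns ``(score, ops)`` where ``ops`` is an int8 array of edit
    operations from start to end: 0 = align a[i]/b[j], 1 = gap in b
    (consume a), 2 = gap in a (consume b).
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + i * gap_extend
        pX[i, 0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        Y[0, j] = gap_open + j * gap_extend
        pY[0, j] = _Y if j > 1 else _M
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[ai, b[j - 1]]
            # match state: best predecessor at (i-1, j-1)
            best = M[i - 1, j - 1]
            ptr = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = _Y
            M[i, j] = best + s
            pM[i, j] = ptr
            # gap in b, consume a[i-1]
            best = M[i - 1, j] + gap_open + gap_extend
            ptr = _M
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                ptr = _X
            if Y[i - 1, j] + gap_open + gap_extend > best:
                best = Y[i - 1, j] + gap_open + gap_extend
                ptr = _Y
            X[i, j] = best
            pX[i, j] = ptr
            # gap in a, consume b[j-1]
            best = M[i, j - 1] + gap_open + gap_extend
            ptr = _M
            if X[i, j - 1] + gap_open + gap_extend > best:
                best = X[i, j - 1] + gap_open + gap_extend
                ptr = _X
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                ptr = _Y
            Y[i, j] = best
            pY[i, j] = ptr
    score = M[n, m]
    state = _M
    if X[n, m] > score:
        score = X[n, m]
        state = _X
    if Y[n, m] > score:
        score = Y[n, m]
        state = _Y
    # traceback
    ops = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == _M:
            ops[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == _X:
            ops[k] = 1
            state = pX[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = pY[i, j]
            j -= 1
    return score, ops[k:]


@njit(cache=False)
def sw_profile(q, pssm, gap_open, gap_extend):
    """Local Smith-Waterman of a sequence against a position-specific matrix.

    ``pssm`` is (n_columns, 21); matching query residue ``r`` to column
    ``c`` scores ``pssm[c, r]``.  Returns ``(score, qstart, qend, cols)``
    where ``cols`` is an int32 array parallel to query positions
    ``qstart..qend-1`` holding the matched profile column or -1 where the
    query residue is an insertion relative to the profile.  A non-positive
    optimum yields ``(0.0, 0, 0, empty)``.
    """
    n = len(q)
    C = pssm.shape[0]
    M = np.full((n + 1, C + 1), NEG_INF)
    X = np.full((n + 1, C + 1), NEG_INF)
    Y = np.full((n + 1, C + 1), NEG_INF)
    pM = np.zeros((n + 1, C + 1), dtype=np.int8)
    pX = np.zeros((n + 1, C + 1), dtype=np.int8)
    pY = np.zeros((n + 1, C + 1), dtype=np.int8)
    best_score = 0.0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, C + 1):
            s = pssm[j - 1, qi]
            prev = 0.0
            ptr = _START
            if M[i - 1, j - 1] > prev:
                prev = M[i - 1, j - 1]
                ptr = _M
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                ptr = _X
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
                ptr = _Y
            M[i, j] = prev + s
            pM[i, j] = ptr
            best = M[i - 1, j] + gap_open + gap_extend
            ptr = _M
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                ptr = _X
            if Y[i - 1, j] + gap_open + gap_extend > best:
                best = Y[i - 1, j] + gap_open + gap_extend
                ptr = _Y
            X[i, j] = best
            pX[i, j] = ptr
            best = M[i, j - 1] + gap_open + gap_extend
            ptr = _M
            if X[i, j - 1] + gap_open + gap_extend > best:
                best = X[i, j - 1] + gap_open + gap_extend
                ptr = _X
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                ptr = _Y
            Y[i, j] = best
            pY[i, j] = ptr
            if M[i, j] > best_score:
                best_score = M[i, j]
                best_i = i
                best_j = j
    cols = np.empty(0, dtype=np.int32)
    if best_score <= 0.0:
        return 0.0, 0, 0, cols
    # traceback from the best match cell; local alignments start and end in
    # the match state
    buf = np.empty(n + C, dtype=np.int32)
    k = n + C
    i, j = best_i, best_j
    state = _M
    qend = best_i
    while True:
        if state == _M:
            k -= 1
            buf[k] = j - 1
            nxt = pM[i, j]
            i -= 1
            j -= 1
            if nxt == _START:
                break
            state = nxt
        elif state == _X:
            k -= 1
            buf[k] = -1
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
    qstart = i
    return best_score, qstart, qend, buf[k:]


@njit(cache=False)
def sw_profile_score(q, pssm, gap_open, gap_extend):
    """Score-only local profile alignment (linear memory, for calibration)."""
    n = len(q)
    C = pssm.shape[0]
    Mprev = np.full(C + 1, NEG_INF)
    Xprev = np.full(C + 1, NEG_INF)
    Yprev = np.full(C + 1, NEG_INF)
    Mcur = np.full(C + 1, NEG_INF)
    Xcur = np.full(C + 1, NEG_INF)
    Ycur = np.full(C + 1, NEG_INF)
    best = 0.0
    for i in range(1, n + 1):
        qi = q[i - 1]
        Mcur[0] = NEG_INF
        Xcur[0] = NEG_INF
        Ycur[0] = NEG_INF
        for j in range(1, C + 1):
            prev = 0.0
            if Mprev[j - 1] > prev:
                prev = Mprev[j - 1]
            if Xprev[j - 1] > prev:
                prev = Xprev[j - 1]
            if Yprev[j - 1] > prev:
                prev = Yprev[j - 1]
            Mcur[j] = prev + pssm[j - 1, qi]
            x = Mprev[j] + gap_open + gap_extend
            if Xprev[j] + gap_extend > x:
                x = Xprev[j] + gap_extend
            if Yprev[j] + gap_open + gap_extend > x:
                x = Yprev[j] + gap_open + gap_extend
            Xcur[j] = x
            y = Mcur[j - 1] + gap_open + gap_extend
            if Xcur[j - 1] + gap_open + gap_extend > y:
                y = Xcur[j - 1] + gap_open + gap_extend
            if Ycur[j - 1] + gap_extend > y:
                y = Ycur[j - 1] + gap_extend
            Ycur[j] = y
            if Mcur[j] > best:
                best = Mcur[j]
        Mprev, Mcur = Mcur, Mprev
        Xprev, Xcur = Xcur, Xprev
        Yprev, Ycur = Ycur, Yprev
    return best
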