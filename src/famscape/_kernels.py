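"""Numba DP kernels for local and global affine-gap alignment.

All kernels use the gap convention cost(k) = gap_open + k * gap_extend for a
gap of length k. Local kernels implement the Smith-Waterman / Gotoh recursion
on a *profile*: the first sequence is represented by an (m, 21) score matrix
whose row i gives the score of profile position i against each residue code,
so the same kernel serves sequence-sequence (rows = substitution-matrix rows)
and PSSM-sequence alignment.

Traceback tie-break order: diagonal, then gap in the first sequence
(horizontal), then gap in the second (vertical).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def local_score(prof, b, gap_open, gap_extend):
    """Best local alignment score of profile ``prof`` vs sequence ``b``."""
    m = prof.shape[0]
    n = b.shape[0]
    go = gap_open + gap_extend
    ge = gap_extend
    h_prev = np.zeros(n + 1)
    e_prev = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, m + 1):
        h_cur = np.zeros(n + 1)
        e_cur = np.full(n + 1, NEG)
        f = NEG
        for j in range(1, n + 1):
            e = max(h_prev[j] - go, e_prev[j] - ge)
            f = max(h_cur[j - 1] - go, f - ge)
            h = h_prev[j - 1] + prof[i - 1, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            e_cur[j] = e
            if h > best:
                best = h
        h_prev = h_cur
        e_prev = e_cur
    return best


@njit(cache=True)
def local_align(prof, b, gap_open, gap_extend):
    """Local alignment with traceback.

    Returns (score, a_start, a_end, b_start, b_end, ai, bi, ncols) where
    ai/bi give, per alignment column, the 0-based position in the profile /
    sequence or -1 for a gap. Coordinates are half-open.
    """
    m = prof.shape[0]
    n = b.shape[0]
    go = gap_open + gap_extend
    ge = gap_extend
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    best = 0.0
    bi_ = 0
    bj_ = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            f = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            h = H[i - 1, j - 1] + prof[i - 1, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi_ = i
                bj_ = j
    # traceback from (bi_, bj_)
    ai = np.empty(m + n, dtype=np.int64)
    bi = np.empty(m + n, dtype=np.int64)
    k = 0
    i = bi_
    j = bj_
    state = 0  # 0=H, 1=E (gap in profile), 2=F (gap in b)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0.0:
                break
            diag = H[i - 1, j - 1] + prof[i - 1, b[j - 1]]
            if h == diag:
                ai[k] = i - 1
                bi[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ai[k] = -1
            bi[k] = j - 1
            k += 1
            if E[i, j] == H[i, j - 1] - go:
                state = 0
            j -= 1
        else:
            ai[k] = i - 1
            bi[k] = -1
            k += 1
            if F[i, j] == H[i - 1, j] - go:
                state = 0
            i -= 1
    # path is reversed
    ai2 = ai[:k][::-1].copy()
    bi2 = bi[:k][::-1].copy()
    a_start = 0
    a_end = 0
    b_start = 0
    b_end = 0
    for t in range(k):
        if ai2[t] >= 0:
            a_end = ai2[t] + 1
        if bi2[t] >= 0:
            b_end = bi2[t] + 1
    for t in range(k - 1, -1, -1):
        if ai2[t] >= 0:
            a_start = ai2[t]
        if bi2[t] >= 0:
            b_start = bi2[t]
    return best, a_start, a_end, b_start, b_end, ai2, bi2, k


@njit(cache=True)
def local_score_from_matrix(S, gap_open, gap_extend):
    """Local affine DP where S[i, j] is the pair score of positions i, j."""
    m, n = S.shape
    go = gap_open + gap_extend
    ge = gap_extend
    h_prev = np.zeros(n + 1)
    e_prev = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, m + 1):
        h_cur = np.zeros(n + 1)
        e_cur = np.full(n + 1, NEG)
        f = NEG
        for j in range(1, n + 1):
            e = max(h_prev[j] - go, e_prev[j] - ge)
            f = max(h_cur[j - 1] - go, f - ge)
            h = h_prev[j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            e_cur[j] = e
            if h > best:
                best = h
        h_prev = h_cur
        e_prev = e_cur
    return best


@njit(cache=True)
def global_align_from_matrix(S, gap_open, gap_extend):
    """Global affine alignment on a pair-score matrix, with traceback.

    Terminal gaps are penalized. Returns (score, ai, bi, ncols) in the same
    path encoding as :func:`local_align`.
    """
    m, n = S.shape
    go = gap_open + gap_extend
    ge = gap_extend
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -go - (j - 1) * ge
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -go - (i - 1) * ge
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            f = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    ai = np.empty(m + n, dtype=np.int64)
    bi = np.empty(m + n, dtype=np.int64)
    k = 0
    i = m
    j = n
    state = 0
    while i > 0 or j > 0:
        if i == 0:
            ai[k] = -1
            bi[k] = j - 1
            k += 1
            j -= 1
            continue
        if j == 0:
            ai[k] = i - 1
            bi[k] = -1
            k += 1
            i -= 1
            continue
        if state == 0:
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            if H[i, j] == diag:
                ai[k] = i - 1
                bi[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ai[k] = -1
            bi[k] = j - 1
            k += 1
            if E[i, j] == H[i, j - 1] - go:
                state = 0
            j -= 1
        else:
            ai[k] = i - 1
            bi[k] = -1
            k += 1
            if F[i, j] == H[i - 1, j] - go:
                state = 0
            i -= 1
    return H[m, n], ai[:k][::-1].copy(), bi[:k][::-1].copy(), k
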