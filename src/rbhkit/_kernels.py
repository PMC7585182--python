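"""Numba kernels for local (Smith-Waterman) protein alignment with affine gaps.

A gap of length L costs ``gap_open + L * gap_extend`` (NCBI BLAST convention:
-gapopen 11 -gapextend 1 charges 12 for a length-1 gap).  Sequences arrive as
int8 arrays of substitution-matrix row indices.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**9))


@njit(cache=True)
def sw_score(a, b, S, go, ge):
    """Best local alignment score and its end cell (score-only, linear memory).

    Returns (score, end_i, end_j) with 1-based ends; the end cell is the
    row-major-first cell attaining the maximum.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros(m + 1, np.int32)
    F = np.zeros(m + 1, np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    oe = np.int32(go + ge)
    for i in range(1, n + 1):
        ai = a[i - 1]
        diag = np.int32(0)
        e = np.int32(0)
        for j in range(1, m + 1):
            up = H[j]
            e1 = H[j - 1] - oe
            e2 = e - ge
            e = e1 if e1 > e2 else e2
            f1 = up - oe
            f2 = F[j] - ge
            f = f1 if f1 > f2 else f2
            h = diag + S[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[j] = h
            F[j] = f
            diag = up
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def sw_score_batch(codes, offsets, qi, si, S, go, ge):
    """Scores for many pairs: pair k aligns sequence qi[k] against si[k].

    `codes`/`offsets` hold all sequences concatenated; sequence t spans
    codes[offsets[t]:offsets[t+1]].
    """
    npairs = qi.shape[0]
    out = np.zeros(npairs, np.int32)
    for k in range(npairs):
        q = codes[offsets[qi[k]]:offsets[qi[k] + 1]]
        s = codes[offsets[si[k]]:offsets[si[k] + 1]]
        sc, _, _ = sw_score(q, s, S, go, ge)
        out[k] = sc
    return out


@njit(cache=True)
def sw_traceback(a, b, S, go, ge):
    """Full DP with traceback.

    Returns (score, q_start, q_end, s_start, s_end, n_identical, n_columns),
    coordinates 1-based inclusive.  Ties during traceback prefer the diagonal
    move, then the vertical (gap in subject), then the horizontal (gap in
    query); gap closure is preferred over gap extension.  Returns score 0 and
    zeroed spans when no positive-scoring alignment exists.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    oe = np.int32(go + ge)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e1 = H[i, j - 1] - oe
            e2 = E[i, j - 1] - ge
            e = e1 if e1 > e2 else e2
            f1 = H[i - 1, j] - oe
            f2 = F[i - 1, j] - ge
            f = f1 if f1 > f2 else f2
            h = H[i - 1, j - 1] + S[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return np.int32(0), 0, 0, 0, 0, 0, 0

    i = bi
    j = bj
    ident = 0
    cols = 0
    state = 0  # 0 = match state, 1 = F (vertical), 2 = E (horizontal)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]:
                cols += 1
                if a[i - 1] == b[j - 1]:
                    ident += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            # vertical: query residue aligned to a gap
            cols += 1
            if F[i, j] == H[i - 1, j] - oe:
                state = 0
            i -= 1
        else:
            cols += 1
            if E[i, j] == H[i, j - 1] - oe:
                state = 0
            j -= 1
    return best, i + 1, bi, j + 1, bj, ident, cols
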