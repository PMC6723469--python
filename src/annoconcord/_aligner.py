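"""Low-level alignment kernels (numba).

Scoring convention: match/mismatch per aligned pair; a gap of length k costs
``gap_open + k * gap_extend`` (first gapped position open+extend, each further
position extend).  N is scored as a mismatch against everything, including N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

NEG_INF = -1.0e30


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A=0 C=1 G=2 T=3, anything else=4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=False)
def sw_score(a, b, match, mismatch, gap_open, gap_extend):
    """Optimal local alignment score under affine gaps (score only, linear memory)."""
    m, n = len(a), len(b)
    H = np.zeros(n + 1, dtype=np.float64)
    E = np.full(n + 1, NEG_INF, dtype=np.float64)
    best = 0.0
    first_gap = gap_open + gap_extend
    for i in range(1, m + 1):
        diag = 0.0
        F = NEG_INF
        h_left = 0.0
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = E[j] - gap_extend
            e2 = H[j] - first_gap
            E[j] = e if e > e2 else e2
            f = F - gap_extend
            f2 = h_left - first_gap
            F = f if f > f2 else f2
            s = match if (ai == b[j - 1] and ai != 4) else mismatch
            h = diag + s
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0.0:
                h = 0.0
            diag = H[j]
            H[j] = h
            h_left = h
            if h > best:
                best = h
    return best


@njit(cache=False)
def sw_align(a, b, match, mismatch, gap_open, gap_extend):
    """Optimal local alignment with traceback.

    Returns (score, q_start, q_end, s_start, s_end, matches, aln_len, gaps,
    gap_opens); end coordinates exclusive, 0-based on the inputs.
    """
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1), dtype=np.float64)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.float64)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.float64)
    # pointers: ptrH 0=stop,1=diag,2=E,3=F ; ptrE/ptrF 0=open(from H),1=extend
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    first_gap = gap_open + gap_extend
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e_ext = E[i][j - 1] - gap_extend
            e_opn = H[i][j - 1] - first_gap
            if e_ext > e_opn:
                E[i][j] = e_ext
                ptrE[i][j] = 1
            else:
                E[i][j] = e_opn
                ptrE[i][j] = 0
            f_ext = F[i - 1][j] - gap_extend
            f_opn = H[i - 1][j] - first_gap
            if f_ext > f_opn:
                F[i][j] = f_ext
                ptrF[i][j] = 1
            else:
                F[i][j] = f_opn
                ptrF[i][j] = 0
            s = match if (ai == b[j - 1] and ai != 4) else mismatch
            h = H[i - 1][j - 1] + s
            p = 1
            if E[i][j] > h:
                h = E[i][j]
                p = 2
            if F[i][j] > h:
                h = F[i][j]
                p = 3
            if h <= 0.0:
                h = 0.0
                p = 0
            H[i][j] = h
            ptrH[i][j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    i = bi
    j = bj
    matches = 0
    aln_len = 0
    gaps = 0
    gap_opens = 0
    state = 0  # 0 follow H, 1 follow E, 2 follow F
    while i > 0 and j > 0:
        if state == 0:
            p = ptrH[i][j]
            if p == 0:
                break
            if p == 1:
                aln_len += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            gaps += 1
            if ptrE[i][j] == 0:
                gap_opens += 1
                state = 0
            j -= 1
        else:
            aln_len += 1
            gaps += 1
            if ptrF[i][j] == 0:
                gap_opens += 1
                state = 0
            i -= 1
    return best, i, bi, j, bj, matches, aln_len, gaps, gap_opens


@njit(cache=False)
def nw_profile_ops(S, gap_open, gap_extend, free_ends):
    """Global (optionally semi-global) affine alignment over a profile score matrix.

    S[i, j] scores aligning column i of profile A against column j of profile B.
    With ``free_ends`` leading and trailing gaps are unpenalised (natural for
    CDS sets whose annotated boundaries differ).  Returns int8 ops from start to
    end: 0 = diagonal, 1 = gap in B (consume A), 2 = gap in A (consume B).
    """
    m, n = S.shape
    M = np.full((m + 1, n + 1), NEG_INF, dtype=np.float64)
    X = np.full((m + 1, n + 1), NEG_INF, dtype=np.float64)  # gap in B, consume A
    Y = np.full((m + 1, n + 1), NEG_INF, dtype=np.float64)  # gap in A, consume B
    # predecessor state for each matrix: 0=M, 1=X, 2=Y
    pM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    first_gap = gap_open + gap_extend
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = 0.0 if free_ends else -first_gap - (i - 1) * gap_extend
        pX[i][0] = 1 if i > 1 else 0
    for j in range(1, n + 1):
        Y[0][j] = 0.0 if free_ends else -first_gap - (j - 1) * gap_extend
        pY[0][j] = 2 if j > 1 else 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # M from diagonal
            b = M[i - 1][j - 1]
            p = 0
            if X[i - 1][j - 1] > b:
                b = X[i - 1][j - 1]
                p = 1
            if Y[i - 1][j - 1] > b:
                b = Y[i - 1][j - 1]
                p = 2
            M[i][j] = b + S[i - 1, j - 1]
            pM[i][j] = p
            # X: consume A (vertical)
            b = M[i - 1][j] - first_gap
            p = 0
            if X[i - 1][j] - gap_extend > b:
                b = X[i - 1][j] - gap_extend
                p = 1
            if Y[i - 1][j] - first_gap > b:
                b = Y[i - 1][j] - first_gap
                p = 2
            X[i][j] = b
            pX[i][j] = p
            # Y: consume B (horizontal)
            b = M[i][j - 1] - first_gap
            p = 0
            if Y[i][j - 1] - gap_extend > b:
                b = Y[i][j - 1] - gap_extend
                p = 2
            if X[i][j - 1] - first_gap > b:
                b = X[i][j - 1] - first_gap
                p = 1
            Y[i][j] = b
            pY[i][j] = p
    ops = np.empty(m + n, dtype=np.int8)
    k = m + n
    if free_ends:
        # best cell on the last row/column; unreached tail becomes free gaps
        bi, bj, bs, bv = m, n, 0, M[m][n]
        for st in range(3):
            v = M[m][n] if st == 0 else (X[m][n] if st == 1 else Y[m][n])
            if v > bv:
                bv = v
                bs = st
        for i in range(1, m + 1):
            for st in range(3):
                v = M[i][n] if st == 0 else (X[i][n] if st == 1 else Y[i][n])
                if v > bv:
                    bv = v
                    bi, bj, bs = i, n, st
        for j in range(1, n + 1):
            for st in range(3):
                v = M[m][j] if st == 0 else (X[m][j] if st == 1 else Y[m][j])
                if v > bv:
                    bv = v
                    bi, bj, bs = m, j, st
        for _ in range(m - bi):
            k -= 1
            ops[k] = 1
        for _ in range(n - bj):
            k -= 1
            ops[k] = 2
        i, j, state = bi, bj, bs
    else:
        i, j = m, n
        state = 0
        bv = M[m][n]
        if X[m][n] > bv:
            bv = X[m][n]
            state = 1
        if Y[m][n] > bv:
            state = 2
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                # only possible via free leading gaps
                break
            ns = pM[i][j]
            k -= 1
            ops[k] = 0
            i -= 1
            j -= 1
            state = ns
        elif state == 1:
            ns = pX[i][j]
            k -= 1
            ops[k] = 1
            i -= 1
            state = ns
        else:
            ns = pY[i][j]
            k -= 1
            ops[k] = 2
            j -= 1
            state = ns
    while i > 0:
        k -= 1
        ops[k] = 1
        i -= 1
    while j > 0:
        k -= 1
        ops[k] = 2
        j -= 1
    return ops[k:]


@njit(cache=False)
def pair_count_matrices(codes, idx_pairs, columns):
    """4x4 substitution-count matrices for leaf pairs over selected columns.

    codes: (n_rows, n_cols) uint8 alignment (0..3 bases, >=4 gap/ambiguous);
    idx_pairs: (n_pairs, 2) row indices; columns: column indices to use.
    """
    n_pairs = idx_pairs.shape[0]
    out = np.zeros((n_pairs, 4, 4), dtype=np.float64)
    for p in range(n_pairs):
        i = idx_pairs[p, 0]
        j = idx_pairs[p, 1]
        for c in columns:
            x = codes[i, c]
            y = codes[j, c]
            if x < 4 and y < 4:
                out[p, x, y] += 1.0
    return out
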