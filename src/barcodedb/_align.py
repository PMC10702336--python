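"""Global pairwise alignment kernel (Needleman-Wunsch, affine gaps).

Numba-compiled three-state (match / gap-in-target / gap-in-query) dynamic
program maximising alignment score, with ties between co-optimal alignments
broken toward more matching columns, and remaining ties toward the diagonal
(aligned) state, so the reported identity is well-defined and deterministic.
The traceback yields the column classes needed to exclude terminal gaps from
the identity denominator.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(1 << 60))


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 character codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@njit(cache=True)
def align_stats(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Return (n_match, n_columns_excluding_terminal_gaps, score).

    A gap of length L costs gap_open + L * gap_extend.  States: 0 = diagonal
    (aligned pair), 1 = gap in b (consumes a), 2 = gap in a (consumes b).
    """
    n = a.shape[0]
    m = b.shape[0]
    S = np.full((3, n + 1, m + 1), NEG, np.int64)
    Q = np.zeros((3, n + 1, m + 1), np.int64)
    P = np.full((3, n + 1, m + 1), -1, np.int8)
    S[0, 0, 0] = 0
    for i in range(1, n + 1):
        S[1, i, 0] = gap_open + gap_extend * i
        P[1, i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        S[2, 0, j] = gap_open + gap_extend * j
        P[2, 0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eq = 1 if ai == b[j - 1] else 0
            sub = match if eq == 1 else mismatch
            # state 0: diagonal step from (i-1, j-1)
            bs = NEG
            bq = np.int64(-1)
            bp = -1
            for p in range(3):
                s = S[p, i - 1, j - 1]
                if s > NEG:
                    q = Q[p, i - 1, j - 1]
                    if s > bs or (s == bs and q > bq):
                        bs = s
                        bq = q
                        bp = p
            if bp >= 0:
                S[0, i, j] = bs + sub
                Q[0, i, j] = bq + eq
                P[0, i, j] = bp
            # state 1: gap column consuming a, from (i-1, j)
            bs = NEG
            bq = np.int64(-1)
            bp = -1
            for p in range(3):
                s = S[p, i - 1, j]
                if s > NEG:
                    s2 = s + (gap_extend if p == 1 else gap_open + gap_extend)
                    q = Q[p, i - 1, j]
                    if s2 > bs or (s2 == bs and q > bq):
                        bs = s2
                        bq = q
                        bp = p
            if bp >= 0:
                S[1, i, j] = bs
                Q[1, i, j] = bq
                P[1, i, j] = bp
            # state 2: gap column consuming b, from (i, j-1)
            bs = NEG
            bq = np.int64(-1)
            bp = -1
            for p in range(3):
                s = S[p, i, j - 1]
                if s > NEG:
                    s2 = s + (gap_extend if p == 2 else gap_open + gap_extend)
                    q = Q[p, i, j - 1]
                    if s2 > bs or (s2 == bs and q > bq):
                        bs = s2
                        bq = q
                        bp = p
            if bp >= 0:
                S[2, i, j] = bs
                Q[2, i, j] = bq
                P[2, i, j] = bp
    # best end state (score, then matches)
    st = 0
    for p in range(1, 3):
        if S[p, n, m] > S[st, n, m] or (
            S[p, n, m] == S[st, n, m] and Q[p, n, m] > Q[st, n, m]
        ):
            st = p
    score = S[st, n, m]
    n_match = Q[st, n, m]
    # traceback recording column states end -> start
    cols = np.empty(n + m, np.int8)
    k = 0
    i = n
    j = m
    s = st
    while i > 0 or j > 0:
        cols[k] = s
        k += 1
        pp = P[s, i, j]
        if s == 0:
            i -= 1
            j -= 1
        elif s == 1:
            i -= 1
        else:
            j -= 1
        s = pp
    # terminal gap runs: cols[k-1] is the first alignment column
    lead = 0
    idx = k - 1
    while idx >= 0 and cols[idx] != 0:
        lead += 1
        idx -= 1
    trail = 0
    idx = 0
    while idx < k and cols[idx] != 0:
        trail += 1
        idx += 1
    internal = k - lead - trail
    if internal < 0:  # alignment entirely gaps (one empty side)
        internal = 0
    return n_match, internal, score
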