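"""JIT-compiled affine-gap Needleman-Wunsch kernel and distance counters.

Sequences are encoded as uint8 codes: A=0, C=1, G=2, T=3; ambiguity codes get
values >= 4 and never score as matches against anything (including
themselves being excluded from distance comparisons).  With A/G and C/T two
apart in the encoding, a substitution is a transition iff |x - y| == 2.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate("ACGTRYSWKMBDHVN"):
    _CODE_LUT[ord(_ch)] = _i
_CODE_LUT[ord("-")] = 200  # gaps only ever appear in already-aligned input

_NEG = -1e30


def encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = _CODE_LUT[arr]
    if (codes == 255).any():
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"non-IUPAC character {seq[bad]!r} at position {bad + 1}")
    return codes


@njit(cache=True)
def nw_affine(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Optimal global alignment; gap of length L costs gap_open + (L-1)*gap_extend.

    Returns (score, pa, pb, ncols) where pa/pb hold per-column sequence
    indices (-1 marks a gap).  Traceback ties prefer diagonal > up > left.
    """
    m = a.shape[0]
    n = b.shape[0]
    M = np.empty((m + 1, n + 1))
    X = np.empty((m + 1, n + 1))  # gap in b (vertical / "up")
    Y = np.empty((m + 1, n + 1))  # gap in a (horizontal / "left")
    M[0, 0] = 0.0
    X[0, 0] = _NEG
    Y[0, 0] = _NEG
    for i in range(1, m + 1):
        M[i, 0] = _NEG
        Y[i, 0] = _NEG
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, n + 1):
        M[0, j] = _NEG
        X[0, j] = _NEG
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = match if ai == b[j - 1] else mismatch
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s

            x = M[i - 1, j] + gap_open
            t = X[i - 1, j] + gap_extend
            if t > x:
                x = t
            t = Y[i - 1, j] + gap_open
            if t > x:
                x = t
            X[i, j] = x

            y = M[i, j - 1] + gap_open
            t = Y[i, j - 1] + gap_extend
            if t > y:
                y = t
            t = X[i, j - 1] + gap_open
            if t > y:
                y = t
            Y[i, j] = y

    pa = np.empty(m + n, np.int32)
    pb = np.empty(m + n, np.int32)
    k = 0
    i = m
    j = n
    state = 0
    score = M[m, n]
    if X[m, n] > score:
        score = X[m, n]
        state = 1
    if Y[m, n] > score:
        score = Y[m, n]
        state = 2
    eps = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            pa[k] = i - 1
            pb[k] = j - 1
            k += 1
            s = match if a[i - 1] == b[j - 1] else mismatch
            target = M[i, j] - s
            if abs(M[i - 1, j - 1] - target) <= eps:
                state = 0
            elif abs(X[i - 1, j - 1] - target) <= eps:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            pa[k] = i - 1
            pb[k] = -1
            k += 1
            target = X[i, j]
            if abs(M[i - 1, j] + gap_open - target) <= eps:
                state = 0
            elif abs(X[i - 1, j] + gap_extend - target) <= eps:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            pa[k] = -1
            pb[k] = j - 1
            k += 1
            target = Y[i, j]
            if abs(M[i, j - 1] + gap_open - target) <= eps:
                state = 0
            elif abs(Y[i, j - 1] + gap_extend - target) <= eps:
                state = 2
            else:
                state = 1
            j -= 1
    # reverse in place
    for t in range(k // 2):
        pa[t], pa[k - 1 - t] = pa[k - 1 - t], pa[t]
        pb[t], pb[k - 1 - t] = pb[k - 1 - t], pb[t]
    return score, pa, pb, k


@njit(cache=True)
def pair_counts(a, b, pa, pb, ncols):  # pragma: no cover
    """Pairwise-deletion substitution counts over an alignment path.

    Returns (compared, different, transitions); columns with a gap or an
    ambiguity code on either side are excluded.
    """
    comp = 0
    diff = 0
    ts = 0
    for c in range(ncols):
        i = pa[c]
        j = pb[c]
        if i < 0 or j < 0:
            continue
        x = np.int32(a[i])
        y = np.int32(b[j])
        if x > 3 or y > 3:
            continue
        comp += 1
        if x != y:
            diff += 1
            d = x - y
            if d == 2 or d == -2:
                ts += 1
    return comp, diff, ts
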