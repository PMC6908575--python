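"""Affine-gap dynamic-programming kernel for bisulfite-aware alignment.

Three-state (match / gap-in-read / gap-in-reference) Gotoh recursion over
integer scores, jitted with numba.  The scoring contract lives in
:mod:`imprintscan.amplicon`; this module only knows about encoded sequences
and a substitution matrix.

Gap cost convention: a gap of length L costs ``gap_open + (L-1) *
gap_extend`` (both passed as positive numbers).  ``free_ref_ends`` makes
leading/trailing unaligned reference free ("fit" alignment of a read
within a longer amplicon reference); the read is always aligned
end-to-end.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 9)

# states: 0 = M (aligned pair), 1 = X (gap in read, ref consumed),
# 2 = Y (gap in ref, read consumed); pointer value = predecessor state


@njit(cache=False)
def dp_matrices(read, ref, submat, gap_open, gap_extend, free_ref_ends):
    n = read.shape[0]
    m = ref.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    PM = np.full((n + 1, m + 1), -1, dtype=np.int8)
    PX = np.full((n + 1, m + 1), -1, dtype=np.int8)
    PY = np.full((n + 1, m + 1), -1, dtype=np.int8)
    M[0, 0] = 0
    for j in range(1, m + 1):
        if free_ref_ends:
            X[0, j] = 0
        else:
            X[0, j] = -(gap_open + (j - 1) * gap_extend)
        PX[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        Y[i, 0] = -(gap_open + (i - 1) * gap_extend)
        PY[i, 0] = 2 if i > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = submat[read[i - 1], ref[j - 1]]
            # M: align read[i-1] to ref[j-1]
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            if best > NEG:
                M[i, j] = best + s
                PM[i, j] = ptr
            # X: gap in read (ref j consumed)
            best = M[i, j - 1] - gap_open
            ptr = 0
            if X[i, j - 1] - gap_extend > best:
                best = X[i, j - 1] - gap_extend
                ptr = 1
            if Y[i, j - 1] - gap_open > best:
                best = Y[i, j - 1] - gap_open
                ptr = 2
            X[i, j] = best
            PX[i, j] = ptr
            # Y: gap in ref (read i consumed)
            best = M[i - 1, j] - gap_open
            ptr = 0
            if Y[i - 1, j] - gap_extend > best:
                best = Y[i - 1, j] - gap_extend
                ptr = 2
            if X[i - 1, j] - gap_open > best:
                best = X[i - 1, j] - gap_open
                ptr = 1
            Y[i, j] = best
            PY[i, j] = ptr
    return M, X, Y, PM, PX, PY


def best_score(M, X, Y, free_ref_ends):
    """Best terminal score and its (column, state), deterministic on ties.

    With free reference ends the alignment may stop at any reference
    column; trailing reference is unaligned rather than a gap, so the X
    state is not a valid terminal there.  Ties prefer the smallest column,
    then state order M, Y.
    """
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    if not free_ref_ends:
        cand = [M[n, m], X[n, m], Y[n, m]]
        state = int(np.argmax(cand))
        return int(cand[state]), m, state
    best, end_j, end_state = NEG - 1, m, 0
    for j in range(m + 1):
        for state, mat in ((0, M), (2, Y)):
            if mat[n, j] > best:
                best, end_j, end_state = int(mat[n, j]), j, state
    return best, end_j, end_state


def traceback(pointers, end_j, end_state, n, free_ref_ends):
    """Recover aligned pairs ``(ref_pos, read_pos)``; ``None`` marks a gap.

    With free reference ends, reference columns before the first or after
    the last read-aligned column are unaligned and omitted.
    """
    PM, PX, PY = pointers
    pairs = []
    i, j, state = n, end_j, end_state
    while i > 0 or j > 0:
        if free_ref_ends and i == 0 and state == 1:
            break  # leading unaligned reference
        if state == 0:
            ptr = int(PM[i, j])
            pairs.append((j - 1, i - 1))
            i, j = i - 1, j - 1
        elif state == 1:
            ptr = int(PX[i, j])
            pairs.append((j - 1, None))
            j -= 1
        else:
            ptr = int(PY[i, j])
            pairs.append((None, i - 1))
            i -= 1
        if i == 0 and j == 0:
            break
        state = ptr
    pairs.reverse()
    return pairs


def align(read_codes, ref_codes, submat, gap_open, gap_extend, free_ref_ends=True):
    """Align encoded read to encoded reference; returns ``(score, pairs)``."""
    read = np.asarray(read_codes, dtype=np.int8)
    ref = np.asarray(ref_codes, dtype=np.int8)
    M, X, Y, PM, PX, PY = dp_matrices(read, ref, submat,
                                      gap_open, gap_extend, free_ref_ends)
    score, end_j, end_state = best_score(M, X, Y, free_ref_ends)
    pairs = traceback((PM, PX, PY), end_j, end_state, len(read), free_ref_ends)
    return score, pairs
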