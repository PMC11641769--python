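"""Numba dynamic-programming kernels shared by the pairwise and profile scanners.

Gap convention throughout: a gap of length ``L`` costs ``gap_open +
(L - 1) * gap_extend`` (the opening position is charged ``gap_open``).
State layout is the three-matrix Gotoh formulation: ``M`` (residues aligned),
``IX`` (row-sequence residue against a gap, the "up" move) and ``IY``
(column-sequence residue against a gap, the "left" move).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30  # effectively -infinity, safe to add to


@njit(cache=False)
def gotoh_global(a, b, submat, gap_open, gap_extend):
    """Fill global affine-gap DP matrices for index-encoded sequences a, b.

    Returns (M, IX, IY) of shape (len(a)+1, len(b)+1).
    """
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    IX = np.full((n + 1, m + 1), NEG)
    IY = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        IX[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        IY[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = submat[ai, b[j - 1]]
            best = M[i - 1, j - 1]
            if IX[i - 1, j - 1] > best:
                best = IX[i - 1, j - 1]
            if IY[i - 1, j - 1] > best:
                best = IY[i - 1, j - 1]
            M[i, j] = s + best
            # gap in b (consume a[i-1])
            x = M[i - 1, j] - gap_open
            if IX[i - 1, j] - gap_extend > x:
                x = IX[i - 1, j] - gap_extend
            if IY[i - 1, j] - gap_open > x:
                x = IY[i - 1, j] - gap_open
            IX[i, j] = x
            # gap in a (consume b[j-1])
            y = M[i, j - 1] - gap_open
            if IY[i, j - 1] - gap_extend > y:
                y = IY[i, j - 1] - gap_extend
            if IX[i, j - 1] - gap_open > y:
                y = IX[i, j - 1] - gap_open
            IY[i, j] = y
    return M, IX, IY


@njit(cache=False)
def profile_local(scores, seq, masked, gap_open, gap_extend):
    """Fill local (Smith–Waterman-style) DP for a position-specific profile.

    ``scores`` is (L, 21): log-odds of residue index per profile column.
    ``seq`` is the index-encoded sequence; ``masked`` marks residues that may
    not take part in any alignment (already assigned to an accepted hit).
    Rows index the sequence, columns the profile.  Alignments start and end in
    the match state.  Returns (M, IX, IY) of shape (n+1, L+1).
    """
    n = seq.shape[0]
    L = scores.shape[0]
    M = np.full((n + 1, L + 1), NEG)
    IX = np.full((n + 1, L + 1), NEG)
    IY = np.full((n + 1, L + 1), NEG)
    for i in range(1, n + 1):
        blocked = masked[i - 1]
        for j in range(1, L + 1):
            if blocked:
                s = NEG
            else:
                s = scores[j - 1, seq[i - 1]]
            best = 0.0
            if M[i - 1, j - 1] > best:
                best = M[i - 1, j - 1]
            if IX[i - 1, j - 1] > best:
                best = IX[i - 1, j - 1]
            if IY[i - 1, j - 1] > best:
                best = IY[i - 1, j - 1]
            v = s + best
            M[i, j] = v if v > NEG / 2 else NEG
            if blocked:
                IX[i, j] = NEG
            else:
                x = M[i - 1, j] - gap_open
                if IX[i - 1, j] - gap_extend > x:
                    x = IX[i - 1, j] - gap_extend
                if IY[i - 1, j] - gap_open > x:
                    x = IY[i - 1, j] - gap_open
                IX[i, j] = x if x > NEG / 2 else NEG
            y = M[i, j - 1] - gap_open
            if IY[i, j - 1] - gap_extend > y:
                y = IY[i, j - 1] - gap_extend
            if IX[i, j - 1] - gap_open > y:
                y = IX[i, j - 1] - gap_open
            IY[i, j] = y if y > NEG / 2 else NEG
    return M, IX, IY


_M, _IX, _IY = 0, 1, 2


def traceback_global(a: str, b: str, M, IX, IY, gap_open: float, gap_extend: float):
    """Deterministic global traceback: on ties prefer diagonal, then up, then left.

    Returns (a_aligned, b_aligned, score).
    """
    i, j = len(a), len(b)
    # final state: prefer M > IX > IY on ties
    score = max(M[i, j], IX[i, j], IY[i, j])
    if M[i, j] == score:
        state = _M
    elif IX[i, j] == score:
        state = _IX
    else:
        state = _IY
    out_a: list[str] = []
    out_b: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = max(M[i - 1, j - 1], IX[i - 1, j - 1], IY[i - 1, j - 1])
            if abs(M[i - 1, j - 1] - target) <= tol:
                state = _M
            elif abs(IX[i - 1, j - 1] - target) <= tol:
                state = _IX
            else:
                state = _IY
            i -= 1
            j -= 1
        elif state == _IX:
            out_a.append(a[i - 1])
            out_b.append("-")
            v = IX[i, j]
            if abs(M[i - 1, j] - gap_open - v) <= tol:
                state = _M
            elif abs(IX[i - 1, j] - gap_extend - v) <= tol:
                state = _IX
            else:
                state = _IY
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            v = IY[i, j]
            if abs(M[i, j - 1] - gap_open - v) <= tol:
                state = _M
            elif abs(IY[i, j - 1] - gap_extend - v) <= tol:
                state = _IY
            else:
                state = _IX
            j -= 1
        if i == 0 and j > 0:
            state = _IY
        elif j == 0 and i > 0:
            state = _IX
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


def traceback_local(M, IX, IY, end_i: int, end_j: int, gap_open: float, gap_extend: float):
    """Trace a local profile hit back from its best match cell.

    Returns (start_i, start_j): 1-based first sequence residue and profile
    column of the hit.  Preference on ties: diagonal continuation from M,
    then IX, then IY, then local start (score 0).
    """
    i, j = end_i, end_j
    state = _M
    tol = 1e-9
    while True:
        if state == _M:
            prevs = (M[i - 1, j - 1], IX[i - 1, j - 1], IY[i - 1, j - 1])
            best_prev = max(prevs[0], prevs[1], prevs[2], 0.0)
            if best_prev == 0.0 and not (max(prevs) > tol):
                return i, j
            if abs(prevs[0] - best_prev) <= tol:
                state = _M
            elif abs(prevs[1] - best_prev) <= tol:
                state = _IX
            else:
                state = _IY
            i -= 1
            j -= 1
        elif state == _IX:
            v = IX[i, j]
            if abs(M[i - 1, j] - gap_open - v) <= tol:
                state = _M
            elif abs(IX[i - 1, j] - gap_extend - v) <= tol:
                state = _IX
            else:
                state = _IY
            i -= 1
        else:
            v = IY[i, j]
            if abs(M[i, j - 1] - gap_open - v) <= tol:
                state = _M
            elif abs(IY[i, j - 1] - gap_extend - v) <= tol:
                state = _IY
            else:
                state = _IX
            j -= 1
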