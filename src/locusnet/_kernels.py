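"""Numba inner loops for HMM inference (Viterbi, summaries, forward-backward).

All kernels work on dense 15-state arrays; forbidden transitions and masked
emissions are -inf in log space / 0.0 in linear space.  Tie-breaks in every
argmax go to the lowest state index (strict ``>`` with ascending scan).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def viterbi_kernel(logE, logA, log_init, final_allowed):
    """Sequential Viterbi. Returns (path, score); score=-inf if no valid path."""
    T, S = logE.shape
    delta = np.empty((T, S), dtype=np.float64)
    bp = np.full((T, S), -1, dtype=np.int8)
    for q in range(S):
        delta[0, q] = log_init[q] + logE[0, q]
    for t in range(1, T):
        for q in range(S):
            best = NEG_INF
            arg = -1
            for p in range(S):
                a = logA[p, q]
                if a == NEG_INF:
                    continue
                v = delta[t - 1, p] + a
                if v > best:
                    best = v
                    arg = p
            if arg >= 0 and best > NEG_INF:
                delta[t, q] = best + logE[t, q]
                bp[t, q] = arg
            else:
                delta[t, q] = NEG_INF
    best = NEG_INF
    arg = -1
    for q in range(S):
        if final_allowed[q] and delta[T - 1, q] > best:
            best = delta[T - 1, q]
            arg = q
    path = np.empty(T, dtype=np.int8)
    if arg < 0:
        return path, NEG_INF
    path[T - 1] = arg
    for t in range(T - 1, 0, -1):
        arg = bp[t, arg]
        path[t - 1] = arg
    return path, best


@njit(cache=True)
def segment_summary_kernel(logE, logA, entry_convention):
    """Max-plus summary M[p,q] of one segment.

    With ``entry_convention`` True (first segment), p is the state at the
    segment's first position: M init is diag(logE[0]).  Otherwise p is the
    state at the last position of the *previous* segment and the entering
    transition is included: M init is logA[p,q] + logE[0,q].
    """
    T, S = logE.shape
    M = np.full((S, S), NEG_INF, dtype=np.float64)
    if entry_convention:
        for p in range(S):
            M[p, p] = logE[0, p]
    else:
        for p in range(S):
            for q in range(S):
                if logA[p, q] != NEG_INF:
                    M[p, q] = logA[p, q] + logE[0, q]
    nxt = np.empty((S, S), dtype=np.float64)
    for t in range(1, T):
        for p in range(S):
            for q in range(S):
                best = NEG_INF
                for r in range(S):
                    a = logA[r, q]
                    if a == NEG_INF:
                        continue
                    v = M[p, r] + a
                    if v > best:
                        best = v
                nxt[p, q] = best + logE[t, q] if best > NEG_INF else NEG_INF
        M[:, :] = nxt
    return M


@njit(cache=True)
def viterbi_with_init_kernel(logE, logA, init_delta):
    """Sequential Viterbi over a segment given the previous boundary scores.

    ``init_delta`` holds the full Viterbi scores at the position immediately
    before the segment.  Returns (delta_last, bp, entry_bp) where entry_bp[q]
    is the previous-boundary argmax for first-position state q.
    """
    T, S = logE.shape
    delta = np.empty((T, S), dtype=np.float64)
    bp = np.full((T, S), -1, dtype=np.int8)
    entry_bp = np.full(S, -1, dtype=np.int8)
    for q in range(S):
        best = NEG_INF
        arg = -1
        for p in range(S):
            a = logA[p, q]
            if a == NEG_INF:
                continue
            v = init_delta[p] + a
            if v > best:
                best = v
                arg = p
        if arg >= 0 and best > NEG_INF:
            delta[0, q] = best + logE[0, q]
            entry_bp[q] = arg
        else:
            delta[0, q] = NEG_INF
    for t in range(1, T):
        for q in range(S):
            best = NEG_INF
            arg = -1
            for p in range(S):
                a = logA[p, q]
                if a == NEG_INF:
                    continue
                v = delta[t - 1, p] + a
                if v > best:
                    best = v
                    arg = p
            if arg >= 0 and best > NEG_INF:
                delta[t, q] = best + logE[t, q]
                bp[t, q] = arg
            else:
                delta[t, q] = NEG_INF
    return delta[T - 1], bp, entry_bp, delta


@njit(cache=True)
def backtrack_segment(bp, entry_bp, exit_state):
    """Reconstruct a segment path from its backpointers; also return the
    previous-boundary state."""
    T = bp.shape[0]
    path = np.empty(T, dtype=np.int8)
    q = exit_state
    path[T - 1] = q
    for t in range(T - 1, 0, -1):
        q = bp[t, q]
        path[t - 1] = q
    prev_boundary = entry_bp[q]
    return path, prev_boundary


@njit(cache=True)
def forward_backward_kernel(E, A, init, final_allowed):
    """Scaled forward-backward on linear-space likelihoods E (T,S).

    Returns (gamma, log_likelihood, first_dead_position); if a forward step
    has zero total mass the first such position is reported and gamma is
    undefined.
    """
    T, S = E.shape
    alpha = np.empty((T, S), dtype=np.float64)
    c = np.empty(T, dtype=np.float64)
    tot = 0.0
    for q in range(S):
        alpha[0, q] = init[q] * E[0, q]
        tot += alpha[0, q]
    if tot <= 0.0:
        return alpha, NEG_INF, 0
    c[0] = tot
    for q in range(S):
        alpha[0, q] /= tot
    for t in range(1, T):
        tot = 0.0
        for q in range(S):
            s = 0.0
            for p in range(S):
                s += alpha[t - 1, p] * A[p, q]
            v = s * E[t, q]
            alpha[t, q] = v
            tot += v
        if tot <= 0.0:
            return alpha, NEG_INF, t
        c[t] = tot
        for q in range(S):
            alpha[t, q] /= tot
    beta = np.empty((T, S), dtype=np.float64)
    for q in range(S):
        beta[T - 1, q] = 1.0 if final_allowed[q] else 0.0
    for t in range(T - 2, -1, -1):
        for p in range(S):
            s = 0.0
            for q in range(S):
                s += A[p, q] * E[t + 1, q] * beta[t + 1, q]
            beta[t, p] = s / c[t + 1]
    gamma = np.empty((T, S), dtype=np.float64)
    for t in range(T):
        tot = 0.0
        for q in range(S):
            v = alpha[t, q] * beta[t, q]
            gamma[t, q] = v
            tot += v
        if tot <= 0.0:
            return gamma, NEG_INF, t
        for q in range(S):
            gamma[t, q] /= tot
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])
    return gamma, ll, -1


@njit(cache=True)
def sample_state_durations(A, state, n_samples, seed):
    """Monte-Carlo run lengths of ``state`` under transition matrix A.

    Each sample enters ``state`` and follows the chain's row until it
    leaves; the run length (number of consecutive visits) is recorded.
    """
    np.random.seed(seed)
    S = A.shape[0]
    out = np.empty(n_samples, dtype=np.int64)
    for i in range(n_samples):
        length = 1
        while True:
            u = np.random.random()
            acc = 0.0
            nxt = S - 1
            for q in range(S):
                acc += A[state, q]
                if u < acc:
                    nxt = q
                    break
            if nxt == state:
                length += 1
            else:
                break
        out[i] = length
    return out
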