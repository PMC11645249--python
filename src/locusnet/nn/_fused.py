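"""Numba kernels for the fused recurrent ops (LSTM and HMM posteriors).

These implement the forward passes and their exact reverse-mode gradients;
both are verified against central finite differences in the test suite.
Array layouts put the time axis first (S, B, ...) so each step is a dense
(B, D) x (D, 4U) matrix product.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lstm_forward(x, Wx, Wh, b):
    """Unidirectional LSTM. x: (S,B,D) -> h: (S,B,U) plus gate caches."""
    S, B, D = x.shape
    U = Wh.shape[0]
    h = np.zeros((S, B, U), x.dtype)
    c = np.zeros((S, B, U), x.dtype)
    gi = np.zeros((S, B, U), x.dtype)
    gf = np.zeros((S, B, U), x.dtype)
    gg = np.zeros((S, B, U), x.dtype)
    go = np.zeros((S, B, U), x.dtype)
    tc = np.zeros((S, B, U), x.dtype)
    h_prev = np.zeros((B, U), x.dtype)
    c_prev = np.zeros((B, U), x.dtype)
    for t in range(S):
        z = np.dot(x[t], Wx) + np.dot(h_prev, Wh) + b
        for bi in range(B):
            for u in range(U):
                i = 1.0 / (1.0 + np.exp(-z[bi, u]))
                f = 1.0 / (1.0 + np.exp(-z[bi, U + u]))
                g = np.tanh(z[bi, 2 * U + u])
                o = 1.0 / (1.0 + np.exp(-z[bi, 3 * U + u]))
                cc = f * c_prev[bi, u] + i * g
                th = np.tanh(cc)
                gi[t, bi, u] = i
                gf[t, bi, u] = f
                gg[t, bi, u] = g
                go[t, bi, u] = o
                c[t, bi, u] = cc
                tc[t, bi, u] = th
                h[t, bi, u] = o * th
        h_prev = h[t]
        c_prev = c[t]
    return h, c, gi, gf, gg, go, tc


@njit(cache=True)
def lstm_backward(x, Wx, Wh, h, c, gi, gf, gg, go, tc, dh_out):
    """Exact BPTT for :func:`lstm_forward` given dL/dh at every step."""
    S, B, D = x.shape
    U = Wh.shape[0]
    dx = np.zeros((S, B, D), x.dtype)
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * U, x.dtype)
    dh_next = np.zeros((B, U), x.dtype)
    dc_next = np.zeros((B, U), x.dtype)
    dz = np.zeros((B, 4 * U), x.dtype)
    for t in range(S - 1, -1, -1):
        for bi in range(B):
            for u in range(U):
                dh = dh_out[t, bi, u] + dh_next[bi, u]
                o = go[t, bi, u]
                th = tc[t, bi, u]
                dc = dh * o * (1.0 - th * th) + dc_next[bi, u]
                i = gi[t, bi, u]
                f = gf[t, bi, u]
                g = gg[t, bi, u]
                c_prev = c[t - 1, bi, u] if t > 0 else 0.0
                dz[bi, u] = dc * g * i * (1.0 - i)
                dz[bi, U + u] = dc * c_prev * f * (1.0 - f)
                dz[bi, 2 * U + u] = dc * i * (1.0 - g * g)
                dz[bi, 3 * U + u] = dh * th * o * (1.0 - o)
                dc_next[bi, u] = dc * f
        dx[t] = np.dot(dz, Wx.T)
        dh_next = np.dot(dz, Wh.T)
        dWx += np.dot(x[t].T, dz)
        if t > 0:
            dWh += np.dot(h[t - 1].T, dz)
        db += dz.sum(axis=0)
    return dx, dWx, dWh, db


@njit(cache=True)
def hmm_posterior_forward(E, A, init, final):
    """Scaled forward-backward over a batch. E: (B,T,S) likelihoods.

    Returns (gamma, alpha, cscale, beta, srow, dead) where dead is the first
    position with zero total forward mass (-1 if none).
    """
    B, T, S = E.shape
    alpha = np.zeros((B, T, S))
    beta = np.zeros((B, T, S))
    gamma = np.zeros((B, T, S))
    cscale = np.zeros((B, T))
    srow = np.zeros((B, T))
    for bi in range(B):
        tot = 0.0
        for q in range(S):
            v = init[q] * E[bi, 0, q]
            alpha[bi, 0, q] = v
            tot += v
        if tot <= 0.0:
            return gamma, alpha, cscale, beta, srow, 0
        cscale[bi, 0] = tot
        for q in range(S):
            alpha[bi, 0, q] /= tot
        for t in range(1, T):
            tot = 0.0
            for q in range(S):
                s = 0.0
                for p in range(S):
                    s += alpha[bi, t - 1, p] * A[p, q]
                v = s * E[bi, t, q]
                alpha[bi, t, q] = v
                tot += v
            if tot <= 0.0:
                return gamma, alpha, cscale, beta, srow, t
            cscale[bi, t] = tot
            for q in range(S):
                alpha[bi, t, q] /= tot
        for q in range(S):
            beta[bi, T - 1, q] = final[q]
        for t in range(T - 2, -1, -1):
            for p in range(S):
                s = 0.0
                for q in range(S):
                    s += A[p, q] * E[bi, t + 1, q] * beta[bi, t + 1, q]
                beta[bi, t, p] = s / cscale[bi, t + 1]
        for t in range(T):
            tot = 0.0
            for q in range(S):
                v = alpha[bi, t, q] * beta[bi, t, q]
                gamma[bi, t, q] = v
                tot += v
            if tot <= 0.0:
                return gamma, alpha, cscale, beta, srow, t
            srow[bi, t] = tot
            for q in range(S):
                gamma[bi, t, q] /= tot
    return gamma, alpha, cscale, beta, srow, -1


@njit(cache=True)
def hmm_posterior_backward(E, A, init, alpha, cscale, beta, gamma, srow, G):
    """Reverse-mode gradient of the posteriors with respect to E.

    G is dL/dgamma; returns dL/dE.  Follows the three stored recursions in
    reverse: normalisation of gamma, the beta recursion (replayed forward in
    t because beta was built backward), then the alpha recursion.
    """
    B, T, S = E.shape
    dE = np.zeros((B, T, S))
    for bi in range(B):
        da = np.zeros((T, S))
        db = np.zeros((T, S))
        dc = np.zeros(T)
        # gamma_t = g'/s with g'_q = a_q b_q, s = sum g':
        # dL/dg'_q = (G_q - sum_p G_p gamma_p) / s
        for t in range(T):
            dot = 0.0
            for q in range(S):
                dot += G[bi, t, q] * gamma[bi, t, q]
            for q in range(S):
                dgp = (G[bi, t, q] - dot) / srow[bi, t]
                da[t, q] += dgp * beta[bi, t, q]
                db[t, q] += dgp * alpha[bi, t, q]
        # beta recursion reverse: b_{t-1} = ((E_t * b_t) @ A^T) / c_t
        for t in range(1, T):
            dotbb = 0.0
            for p in range(S):
                dotbb += db[t - 1, p] * beta[bi, t - 1, p]
            dc[t] += -dotbb / cscale[bi, t]
            for q in range(S):
                w = 0.0
                for p in range(S):
                    w += db[t - 1, p] * A[p, q]
                w /= cscale[bi, t]
                db[t, q] += w * E[bi, t, q]
                dE[bi, t, q] += w * beta[bi, t, q]
        # alpha recursion reverse: a'_t = (a_{t-1} @ A) * E_t ; a_t = a'/c
        for t in range(T - 1, -1, -1):
            dota = 0.0
            for q in range(S):
                dota += da[t, q] * alpha[bi, t, q]
            shift = dc[t] - dota / cscale[bi, t]
            if t > 0:
                for q in range(S):
                    m = 0.0
                    for p in range(S):
                        m += alpha[bi, t - 1, p] * A[p, q]
                    dap = da[t, q] / cscale[bi, t] + shift
                    dE[bi, t, q] += dap * m
                for p in range(S):
                    acc = 0.0
                    for q in range(S):
                        acc += (da[t, q] / cscale[bi, t] + shift) * E[bi, t, q] * A[p, q]
                    da[t - 1, p] += acc
            else:
                for q in range(S):
                    dap = da[0, q] / cscale[bi, 0] + shift
                    dE[bi, 0, q] += dap * init[q]
    return dE
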