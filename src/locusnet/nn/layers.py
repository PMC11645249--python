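"""Network building blocks: dense, 1-D convolution, biLSTM, Adam.

Weights are float64 :class:`~locusnet.nn.autodiff.Tensor` parameters.
Initialisation is Glorot-uniform from a caller-supplied generator so runs
are reproducible from a single seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from ._fused import lstm_backward, lstm_forward


class Layer:
    def parameters(self) -> List[Tensor]:
        return []

    def __call__(self, x: Tensor) -> Tensor:
        raise NotImplementedError

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i}"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = ad.parameter(_glorot(rng, n_in, n_out, (n_in, n_out)))
        self.b = ad.parameter(np.zeros(n_out))

    def parameters(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.W) + self.b


class Conv1d(Layer):
    """Same-padded stride-1 convolution over (B, T, C) inputs."""

    def __init__(self, n_in: int, n_filters: int, width: int, rng: np.random.Generator):
        self.width = width
        self.W = ad.parameter(
            _glorot(rng, n_in * width, n_filters, (width, n_in, n_filters))
        )
        self.b = ad.parameter(np.zeros(n_filters))

    def parameters(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        # conv as K shifted matmuls: fast BLAS paths, no window copies
        K = self.width
        pl = K // 2
        W, b = self.W, self.b
        xd = x.data
        Bsz, T, C = xd.shape
        xp = np.pad(xd, ((0, 0), (pl, K - 1 - pl), (0, 0)))
        out = np.broadcast_to(b.data, (Bsz, T, b.data.shape[0])).copy()
        for k in range(K):
            out += xp[:, k : k + T, :] @ W.data[k]

        def backward(g):
            dW = np.empty_like(W.data)
            dxp = np.zeros_like(xp)
            flat_g = g.reshape(-1, g.shape[-1])
            for k in range(K):
                seg = xp[:, k : k + T, :].reshape(-1, C)
                dW[k] = seg.T @ flat_g
                dxp[:, k : k + T, :] += g @ W.data[k].T
            db = flat_g.sum(axis=0)
            return dxp[:, pl : pl + T, :], dW, db

        return ad.custom_op(out, (x, W, b), backward)


class BiLSTM(Layer):
    """Bidirectional LSTM over (B, S, D); outputs (B, S, 2U)."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.params: List[Tensor] = []
        self._dirs = []
        for _ in range(2):
            Wx = ad.parameter(_glorot(rng, n_in, 4 * units, (n_in, 4 * units)))
            Wh = ad.parameter(_glorot(rng, units, 4 * units, (units, 4 * units)))
            b = np.zeros(4 * units)
            b[units : 2 * units] = 1.0  # forget-gate bias
            bp = ad.parameter(b)
            self._dirs.append((Wx, Wh, bp))
            self.params.extend([Wx, Wh, bp])

    def parameters(self):
        return list(self.params)

    def __call__(self, x: Tensor) -> Tensor:
        xd = np.ascontiguousarray(np.swapaxes(x.data, 0, 1))  # (S,B,D)
        outs = []
        caches = []
        for d, (Wx, Wh, b) in enumerate(self._dirs):
            xin = xd if d == 0 else xd[::-1].copy()
            h, c, gi, gf, gg, go, tc = lstm_forward(xin, Wx.data, Wh.data, b.data)
            caches.append((xin, h, c, gi, gf, gg, go, tc))
            outs.append(h if d == 0 else h[::-1])
        out = np.concatenate(outs, axis=2)  # (S,B,2U)
        out = np.swapaxes(out, 0, 1).copy()  # (B,S,2U)
        U = self.units
        dirs = self._dirs

        def backward(g):
            gs = np.swapaxes(g, 0, 1)  # (S,B,2U)
            grads = [None] * 7
            dx_total = None
            for d, (Wx, Wh, b) in enumerate(dirs):
                xin, h, c, gi, gf, gg, go, tc = caches[d]
                gd = gs[:, :, d * U : (d + 1) * U]
                gd = np.ascontiguousarray(gd if d == 0 else gd[::-1])
                dx, dWx, dWh, db = lstm_backward(
                    xin, Wx.data, Wh.data, h, c, gi, gf, gg, go, tc, gd
                )
                if d == 1:
                    dx = dx[::-1]
                dx_total = dx if dx_total is None else dx_total + dx
                grads[1 + 3 * d : 4 + 3 * d] = [dWx, dWh, db]
            grads[0] = np.swapaxes(dx_total, 0, 1)
            return grads

        return ad.custom_op(out, (x, *self.params), backward)


class Adam:
    """Adaptive-moment (Adam) optimiser with global-norm gradient clipping."""

    def __init__(
        self,
        params: Sequence[Tensor],
        learning_rate: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0
        self.clip_norm = 1.0

    def step(self) -> None:
        self.t += 1
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad * p.grad).sum())
        norm = np.sqrt(total)
        scale = self.clip_norm / norm if self.clip_norm and norm > self.clip_norm else 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
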