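"""The CCE-F1 training loss and its components.

Coding bases are ~1% of a mammalian genome, so plain cross-entropy barely
sees the classes that matter for gene structure.  The combined loss is

    CCE-F1 = CCE + λ · ( F1-loss   if the sequence contains exon labels
                         FPR̂       otherwise ),

computed per sequence and averaged over a batch, with λ = 2 by default.
``F1-loss`` sums ``1 − F1̂_i`` over the 11 exon classes present in the
sequence, where ``F1̂_i`` is a differentiable soft F1 built from soft counts
(TP̂_i = Σ_j Ŷ[j,i]·Y[j,i]); for exon-free sequences the estimated false
positive rate FPR̂ — the mean predicted exon-class mass per position —
replaces it.  CCE is a position-mean with the predicted probability floored
at 1e-12.

Every function accepts plain numpy arrays (returning floats) or autodiff
:class:`~locusnet.nn.autodiff.Tensor` inputs (returning Tensors, so the
training loops backpropagate through the same code that the tests check).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple, Union

import numpy as np

from . import alphabet as ab
from .alphabet import ALPHABET
from .hmm import ClassProbMatrix
from .label_codec import LabelSequence
from .nn import autodiff as ad
from .nn.autodiff import Tensor

__all__ = [
    "LossConfig",
    "categorical_cross_entropy",
    "soft_f1_scores",
    "f1_loss",
    "estimated_fpr",
    "cce_f1_loss",
]

PROB_FLOOR = 1e-12


@dataclass
class LossConfig:
    lambda_weight: float = 2.0
    exon_class_indices: Tuple[int, ...] = ALPHABET.exon_class_indices

    def __post_init__(self) -> None:
        if self.lambda_weight < 0:
            raise ValueError("lambda must be nonnegative")


ArrayLike = Union[np.ndarray, Tensor, ClassProbMatrix]


def _as_probs(Yhat: ArrayLike) -> Tuple[Tensor, bool]:
    if isinstance(Yhat, Tensor):
        return Yhat, True
    if isinstance(Yhat, ClassProbMatrix):
        Yhat = Yhat.probabilities
    return Tensor(np.asarray(Yhat, dtype=np.float64)), False


def _as_onehot(Y_true, T: int) -> np.ndarray:
    if isinstance(Y_true, LabelSequence):
        Y_true = Y_true.labels
    arr = np.asarray(Y_true)
    if arr.ndim == 2:
        return arr.astype(np.float64)
    onehot = np.zeros((T, ab.N_STATES))
    onehot[np.arange(T), arr.astype(int)] = 1.0
    return onehot


def _ret(x: Tensor, was_tensor: bool):
    return x if was_tensor else float(x.item())


def categorical_cross_entropy(Y_true, Yhat: ArrayLike):
    """Position-mean negative log predicted probability of the true label."""
    yh, keep = _as_probs(Yhat)
    onehot = _as_onehot(Y_true, yh.shape[0])
    picked = ad.tsum(ad.mul(ad.log(ad.clip_min(yh, PROB_FLOOR)), ad.constant(onehot)))
    return _ret(ad.mul(picked, -1.0 / yh.shape[0]), keep)


def soft_f1_scores(Y_true, Yhat: ArrayLike, exon_class_indices: Sequence[int] | None = None):
    """Per-exon-class soft F1̂_i = 2·TP̂_i / (P̂_i + A_i), with 0/0 → 0."""
    idx = list(exon_class_indices or ALPHABET.exon_class_indices)
    yh, keep = _as_probs(Yhat)
    onehot = _as_onehot(Y_true, yh.shape[0])[:, idx]
    yc = yh[(slice(None), idx)]
    tp = ad.tsum(ad.mul(yc, ad.constant(onehot)), axis=0)
    pred_mass = ad.tsum(yc, axis=0)
    actual = onehot.sum(axis=0)
    denom = ad.add(pred_mass, ad.constant(actual))
    nonzero = (denom.data > 0).astype(np.float64)
    f1 = ad.mul(
        ad.mul(ad.mul(tp, 2.0), ad.power(ad.clip_min(denom, PROB_FLOOR), -1.0)),
        ad.constant(nonzero),
    )
    return f1 if keep else f1.data.copy()


def f1_loss(Y_true, Yhat: ArrayLike, config: LossConfig | None = None):
    """Sum of (1 − F1̂_i) over the exon classes present in Y_true."""
    config = config or LossConfig()
    idx = list(config.exon_class_indices)
    yh, keep = _as_probs(Yhat)
    onehot = _as_onehot(Y_true, yh.shape[0])
    present = (onehot[:, idx].sum(axis=0) > 0).astype(np.float64)
    f1 = soft_f1_scores(Y_true, yh, idx)
    loss = ad.tsum(ad.mul(ad.add(ad.mul(f1, -1.0), 1.0), ad.constant(present)))
    return _ret(loss, keep)


def estimated_fpr(Yhat: ArrayLike, exon_class_indices: Sequence[int] | None = None):
    """Mean predicted exon-class mass per position, FPR̂ = (1/T)·Σ_i Σ_j Ŷ[j,i]."""
    idx = list(exon_class_indices or ALPHABET.exon_class_indices)
    yh, keep = _as_probs(Yhat)
    total = ad.tsum(yh[(slice(None), idx)])
    return _ret(ad.mul(total, 1.0 / yh.shape[0]), keep)


def cce_f1_loss(Y_true, Yhat, config: LossConfig | None = None):
    """Per-sequence CCE + λ·(F1-loss | FPR̂); batch inputs are averaged.

    ``Yhat`` may be (T,15) or a batch (B,T,15); ``Y_true`` correspondingly
    (T,) or (B,T) label indices (or one-hot with one extra dimension).
    """
    config = config or LossConfig()
    yh, keep = _as_probs(Yhat)
    if yh.ndim == 3:
        return _ret(_batch_loss(Y_true, yh, config), keep)
    return _ret(_sequence_loss(Y_true, yh, config), keep)


def _batch_onehot(Y_true, B: int, T: int) -> np.ndarray:
    labels = Y_true.labels if isinstance(Y_true, LabelSequence) else np.asarray(Y_true)
    if labels.ndim == 3:
        return labels.astype(np.float64)
    onehot = np.zeros((B, T, ab.N_STATES))
    b_idx = np.repeat(np.arange(B), T)
    onehot[b_idx, np.tile(np.arange(T), B), labels.astype(int).ravel()] = 1.0
    return onehot


def _batch_loss(Y_true, yh: Tensor, config: LossConfig) -> Tensor:
    """Vectorised per-sequence CCE-F1 over a (B, T, 15) batch."""
    B, T, _ = yh.shape
    idx = list(config.exon_class_indices)
    onehot = _batch_onehot(Y_true, B, T)
    logp = ad.log(ad.clip_min(yh, PROB_FLOOR))
    cce = ad.mul(ad.tsum(ad.mul(logp, ad.constant(onehot)), axis=(1, 2)), -1.0 / T)
    yc = yh[(slice(None), slice(None), idx)]
    oc = onehot[:, :, idx]
    tp = ad.tsum(ad.mul(yc, ad.constant(oc)), axis=1)           # (B, 11)
    pred_mass = ad.tsum(yc, axis=1)                              # (B, 11)
    actual = oc.sum(axis=1)                                      # (B, 11)
    denom = ad.add(pred_mass, ad.constant(actual))
    present = (actual > 0).astype(np.float64)
    f1 = ad.mul(
        ad.mul(ad.mul(tp, 2.0), ad.power(ad.clip_min(denom, PROB_FLOOR), -1.0)),
        ad.constant(present),
    )
    f1_term = ad.tsum(ad.mul(ad.add(ad.mul(f1, -1.0), 1.0), ad.constant(present)), axis=1)
    fpr_term = ad.mul(ad.tsum(yc, axis=(1, 2)), 1.0 / T)
    has_exon = (present.sum(axis=1) > 0).astype(np.float64)
    tail = ad.add(
        ad.mul(f1_term, ad.constant(has_exon)),
        ad.mul(fpr_term, ad.constant(1.0 - has_exon)),
    )
    per_seq = ad.add(cce, ad.mul(tail, config.lambda_weight))
    return ad.mul(ad.tsum(per_seq), 1.0 / B)


def _sequence_loss(Y_true, yh: Tensor, config: LossConfig) -> Tensor:
    onehot = _as_onehot(Y_true, yh.shape[0])
    cce = categorical_cross_entropy(onehot, yh)
    has_exon = onehot[:, list(config.exon_class_indices)].sum() > 0
    if has_exon:
        tail = f1_loss(onehot, yh, config)
    else:
        tail = estimated_fpr(yh, config.exon_class_indices)
    return ad.add(cce, ad.mul(tail, config.lambda_weight))
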