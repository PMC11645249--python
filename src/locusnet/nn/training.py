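"""Training loops: pre-HMM supervised training and HMM-coupled fine-tuning.

Phase one trains the CNN-biLSTM on windows with the CCE-F1 loss applied to
the raw class probabilities.  Phase two fine-tunes end-to-end: the loss is
applied to the HMM's forward–backward posteriors of the network output, so
gradients flow through the (fixed) HMM into the network.  Both loops use
Adam, are deterministic given the seed, and checkpoint the weights with the
best validation combined exon + gene F1 (falling back to training loss when
no validation set is supplied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .. import alphabet as ab
from ..hmm import (
    ConstraintMask,
    HMMParameters,
    emission_likelihoods,
    sequence_constraint_masks,
)
from . import autodiff as ad
from .autodiff import Tensor
from .hmm_layer import hmm_posteriors, masked_likelihoods
from .layers import Adam
from .network import SequenceClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "RandomCropSampler",
    "train_pre_hmm",
    "fine_tune_with_hmm",
]


@dataclass
class TrainingConfig:
    """Optimisation settings.

    ``genic_fraction`` oversamples windows that contain exon labels: coding
    sequence is ~1% of the genome, so uniform window sampling shows the
    optimiser almost nothing but intergenic windows, whose FPR̂ loss term
    only suppresses exon predictions.  Each batch draws this fraction from
    genic windows (when any exist); the remainder is drawn uniformly.
    """

    window_length: int = 9999
    batch_size: int = 8
    learning_rate: float = 1e-4
    max_steps: int = 300
    validation_interval: int = 1000
    genic_fraction: float = 0.5
    grad_clip_norm: float = 5.0
    lr_final_fraction: float = 1.0  # cosine-decay floor as a fraction of learning_rate
    seed: int = 0

    def lr_at(self, step: int) -> float:
        if self.lr_final_fraction >= 1.0:
            return self.learning_rate
        lo = self.learning_rate * self.lr_final_fraction
        t = (step - 1) / max(self.max_steps - 1, 1)
        return lo + 0.5 * (self.learning_rate - lo) * (1.0 + np.cos(np.pi * t))

    def __post_init__(self) -> None:
        if self.window_length % 3 != 0:
            raise ValueError("window length must be divisible by 3 and reshape_factor")


@dataclass
class TrainingHistory:
    losses: List[float] = field(default_factory=list)
    validation_scores: List[Tuple[int, float]] = field(default_factory=list)
    best_step: int = -1
    best_score: float = -np.inf


Dataset = Sequence[Tuple[np.ndarray, np.ndarray]]  # (window x 6 encoding, labels)


class RandomCropSampler:
    """Sample training windows at random offsets from whole-strand arrays.

    Fixed, seamless windows let a small network memorise the absolute
    window framing (e.g. through the distance to the LSTM's reset state)
    and fail on any other framing at inference.  Random crops remove that
    shortcut.  Genic crops are drawn to overlap a uniformly chosen gene
    span, implementing the same oversampling as ``genic_fraction``.
    """

    def __init__(self, strand_data: Dataset, window_length: int):
        self.items = [(np.asarray(e), np.asarray(l)) for e, l in strand_data]
        self.window = window_length
        self.gene_spans: List[Tuple[int, int, int]] = []
        for i, (_, lab) in enumerate(self.items):
            non_ir = np.flatnonzero(lab != ab.IR)
            if non_ir.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(non_ir) > 1)
            starts = np.concatenate([[non_ir[0]], non_ir[breaks + 1]])
            ends = np.concatenate([non_ir[breaks] + 1, [non_ir[-1] + 1]])
            self.gene_spans.extend((i, int(s), int(e)) for s, e in zip(starts, ends))

    def _genic_start(self, rng: np.random.Generator) -> Tuple[int, int]:
        i, s, e = self.gene_spans[rng.integers(len(self.gene_spans))]
        T = self.items[i][0].shape[0]
        lo = max(0, s - self.window + 1)
        hi = min(max(e - 1, lo), T - self.window)
        return i, int(rng.integers(lo, hi + 1))

    def sample(self, config: TrainingConfig, rng: np.random.Generator):
        n_genic = int(round(config.genic_fraction * config.batch_size))
        if not self.gene_spans:
            n_genic = 0
        X, y = [], []
        for k in range(config.batch_size):
            if k < n_genic:
                i, start = self._genic_start(rng)
            else:
                i = int(rng.integers(len(self.items)))
                start = int(rng.integers(0, self.items[i][0].shape[0] - self.window + 1))
            enc, lab = self.items[i]
            X.append(enc[start : start + self.window])
            y.append(lab[start : start + self.window])
        return np.stack(X).astype(ad.default_dtype()), np.stack(y)

    def batches(self, config: TrainingConfig, rng: np.random.Generator):
        while True:
            yield self.sample(config, rng)


def _batches(dataset: Dataset, config: TrainingConfig, rng: np.random.Generator):
    if isinstance(dataset, RandomCropSampler):
        yield from dataset.batches(config, rng)
        return
    exon_idx = np.array(ab.ALPHABET.exon_class_indices)
    genic = np.array([bool(np.isin(d[1], exon_idx).any()) for d in dataset])
    genic_pool = np.flatnonzero(genic)
    n_genic = int(round(config.genic_fraction * config.batch_size))
    if genic_pool.size == 0 or genic_pool.size == len(dataset):
        n_genic = 0
    while True:
        idx = rng.integers(0, len(dataset), size=config.batch_size)
        if n_genic:
            idx[:n_genic] = genic_pool[rng.integers(0, genic_pool.size, size=n_genic)]
        X = np.stack([dataset[i][0] for i in idx]).astype(ad.default_dtype())
        y = np.stack([dataset[i][1] for i in idx])
        yield X, y


def _check_finite(loss: float, step: int) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged: loss {loss} at step {step}")


def _run_loop(
    model: SequenceClassifier,
    dataset: Dataset,
    loss_config,
    config: TrainingConfig,
    loss_fn: Callable[[np.ndarray, np.ndarray], Tensor],
    validate: Optional[Callable[[SequenceClassifier], float]],
) -> TrainingHistory:
    model.config.validate_length(config.window_length)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), learning_rate=config.learning_rate)
    optimizer.clip_norm = config.grad_clip_norm
    history = TrainingHistory()
    best_state = model.state_dict()
    batches = _batches(dataset, config, rng)
    for step in range(1, config.max_steps + 1):
        X, y = next(batches)
        optimizer.lr = config.lr_at(step)
        optimizer.zero_grad()
        loss = loss_fn(X, y)
        value = loss.item()
        _check_finite(value, step)
        loss.backward()
        optimizer.step()
        history.losses.append(value)
        at_interval = step % config.validation_interval == 0 or step == config.max_steps
        if at_interval:
            if validate is not None:
                score = validate(model)
                history.validation_scores.append((step, score))
                logger.info("step %d loss %.4f validation F1 sum %.4f", step, value, score)
            else:
                recent = -float(np.mean(history.losses[-20:]))
                score = recent
            if score > history.best_score:
                history.best_score = score
                history.best_step = step
                best_state = model.state_dict()
    model.load_state_dict(best_state)
    return history


def train_pre_hmm(
    model: SequenceClassifier,
    dataset: Dataset,
    loss_config: "LossConfig | None" = None,
    config: TrainingConfig | None = None,
    validate: Optional[Callable[[SequenceClassifier], float]] = None,
) -> TrainingHistory:
    """Phase one: minimise CCE-F1 on raw network outputs (no HMM layer)."""
    from ..losses import LossConfig, cce_f1_loss

    loss_config = loss_config or LossConfig()
    config = config or TrainingConfig()

    def loss_fn(X, y):
        probs = model.forward(Tensor(X))
        return cce_f1_loss(y, probs, loss_config)

    return _run_loop(model, dataset, loss_config, config, loss_fn, validate)


def fine_tune_with_hmm(
    model: SequenceClassifier,
    hmm_params: HMMParameters,
    dataset: Dataset,
    loss_config: "LossConfig | None" = None,
    config: TrainingConfig | None = None,
    validate: Optional[Callable[[SequenceClassifier], float]] = None,
) -> TrainingHistory:
    """Phase two: minimise CCE-F1 on HMM posteriors, end to end.

    The dataset windows carry their own sequences implicitly through the
    one-hot encoding, from which the constraint masks are rebuilt; HMM
    parameters are fixed, only network weights move.
    """
    from ..losses import LossConfig, cce_f1_loss

    loss_config = loss_config or LossConfig()
    config = config or TrainingConfig()
    eps = hmm_params.emission_smoothing

    def loss_fn(X, y):
        probs = model.forward(Tensor(X))
        masks = np.stack([_mask_from_encoding(X[b]) for b in range(X.shape[0])])
        lik = masked_likelihoods(probs, masks, eps)
        posterior = hmm_posteriors(lik, hmm_params, boundary="free")
        return cce_f1_loss(y, posterior, loss_config)

    return _run_loop(model, dataset, loss_config, config, loss_fn, validate)


_BASES = np.array(list("ACGTN"))


def _mask_from_encoding(encoding: np.ndarray) -> np.ndarray:
    """Recover the sequence from a one-hot encoding and build its mask."""
    seq = "".join(_BASES[np.argmax(encoding[:, :5], axis=1)])
    return sequence_constraint_masks(seq).mask
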