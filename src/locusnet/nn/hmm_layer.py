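"""The HMM as a differentiable layer: batched posteriors with gradients.

During fine-tuning the loss is computed on the forward–backward posterior
probabilities of the network's class probabilities, so gradients must flow
*through* the HMM into the network while the HMM's own 24 parameters stay
fixed.  The forward pass is the scaled forward–backward recursion; the
backward pass replays the recursions in reverse (see
``locusnet/nn/_fused.py``) and is checked against finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .. import alphabet as ab
from ..hmm import ConstraintMask, HMMParameters, DecodingError, _boundary_vectors
from . import autodiff as ad
from .autodiff import Tensor
from ._fused import hmm_posterior_backward, hmm_posterior_forward

__all__ = ["hmm_posteriors", "masked_likelihoods"]


def masked_likelihoods(
    X: Tensor, masks: np.ndarray, epsilon: float
) -> Tensor:
    """Emission likelihoods ``mask · ((1−ε)·X + ε/15)`` as a Tensor op.

    ``X`` is (B, T, 15) network output; ``masks`` the matching stack of
    binary sequence-constraint masks.
    """
    smoothed = ad.add(ad.mul(X, 1.0 - epsilon), epsilon / ab.N_STATES)
    return ad.mul(smoothed, ad.constant(np.asarray(masks, dtype=np.float64)))


def hmm_posteriors(
    likelihoods: Tensor,
    params: HMMParameters,
    boundary: str = "free",
) -> Tensor:
    """Batched posterior state probabilities, differentiable in the input.

    Training windows are seamless tiles that may start or end inside a
    gene, so the default boundary condition is free at both ends.
    """
    E = np.ascontiguousarray(likelihoods.data)
    if E.ndim == 2:
        E = E[None]
    init, final = _boundary_vectors(params, boundary)
    A = params.transition_matrix
    gamma, alpha, cscale, beta, srow, dead = hmm_posterior_forward(
        E, A, init, final.astype(np.float64)
    )
    if dead >= 0:
        raise DecodingError(dead)

    def backward(g):
        G = np.ascontiguousarray(g)
        dE = hmm_posterior_backward(E, A, init, alpha, cscale, beta, gamma, srow, G)
        if likelihoods.data.ndim == 2:
            dE = dE[0]
        return (dE,)

    out = gamma if likelihoods.data.ndim == 3 else gamma[0]
    return ad.custom_op(out, (likelihoods,), backward)
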