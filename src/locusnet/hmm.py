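"""The fixed 24-parameter gene-structure HMM.

The HMM has the 15 states of :mod:`locusnet.alphabet` and support on exactly
23 transition edges; its only free parameters are the 23 transition
probabilities (set from mean region lengths so that self-loops realise
geometric length distributions with the configured means) and a single
emission smoothing value ε.  The emission distribution maps the 15 network
output classes one-to-one onto the states,

    likelihood[i, q] = mask[i, q] * ((1 - ε) * X[i, q] + ε / 15),

where the binary sequence-constraint mask enforces canonical gene signals:
ATG at START, a stop triplet ending at STOP, GT after a donor, AG before an
acceptor, and no in-frame stop triplet at an exonic codon-position-2 state.
Stops spliced across an intron are not representable in a per-position mask
and are handled by a post-filter downstream.

The HMM itself is never trained; posteriors are differentiable in the input
class probabilities (see :mod:`locusnet.nn.hmm_layer` for the training-time
pass).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import alphabet as ab
from .alphabet import ALPHABET, StateAlphabet
from .io_formats import GenomeRecord
from ._kernels import forward_backward_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "HMMParameters",
    "ConstraintMask",
    "ClassProbMatrix",
    "build_transitions",
    "sequence_constraint_masks",
    "emission_likelihoods",
    "forward_backward",
    "DecodingError",
]

STOP_TRIPLETS = ("TAA", "TAG", "TGA")

#: default mean region lengths (bases); see SimulationConfig for their origin
DEFAULT_MEAN_LENGTHS = {"intergenic": 62250.0, "intron": 3000.0, "coding_exon": 150.0}


class DecodingError(RuntimeError):
    """No positive-probability path exists (typically over-masking)."""

    def __init__(self, position: int):
        super().__init__(
            f"all states have zero probability at position {position}; "
            "the constraint mask admits no path"
        )
        self.position = position


@dataclass
class HMMParameters:
    """Transition structure, initial distribution and emission smoothing."""

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    emission_smoothing: float
    mean_lengths: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.transition_matrix, dtype=np.float64)
        if A.shape != (ab.N_STATES, ab.N_STATES):
            raise ValueError(f"transition matrix must be 15x15, got {A.shape}")
        adj = ALPHABET.adjacency()
        if np.any(A[~adj] != 0.0):
            raise ValueError("transition mass outside the 23-edge support")
        rows = A.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError(f"transition rows must sum to 1, got {rows}")
        if not (0.0 <= self.emission_smoothing < 1.0):
            raise ValueError("emission smoothing must lie in [0, 1)")
        self.transition_matrix = A
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=np.float64)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.transition_matrix))

    @property
    def n_free_parameters(self) -> int:
        """23 transition values plus the emission smoothing."""
        return self.n_edges + 1

    @property
    def log_transitions(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.transition_matrix)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "transition_matrix": self.transition_matrix.tolist(),
                    "initial_distribution": self.initial_distribution.tolist(),
                    "emission_smoothing": self.emission_smoothing,
                    "mean_lengths": self.mean_lengths,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "HMMParameters":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            transition_matrix=np.array(d["transition_matrix"]),
            initial_distribution=np.array(d["initial_distribution"]),
            emission_smoothing=d["emission_smoothing"],
            mean_lengths=d.get("mean_lengths", {}),
        )


@dataclass
class ConstraintMask:
    """T×15 binary matrix; 1 = state allowed at the position."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.ndim != 2 or self.mask.shape[1] != ab.N_STATES:
            raise ValueError(f"mask must be T x 15, got {self.mask.shape}")


@dataclass
class ClassProbMatrix:
    """T×15 row-stochastic matrix of per-position class probabilities."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.probabilities, dtype=np.float64)
        if P.ndim != 2 or P.shape[1] != ab.N_STATES:
            raise ValueError(f"class probabilities must be T x 15, got {P.shape}")
        self.probabilities = P

    def __len__(self) -> int:
        return len(self.probabilities)


def build_transitions(
    mean_lengths: Optional[Dict[str, float]] = None,
    alphabet: StateAlphabet = ALPHABET,
    emission_smoothing: float = 0.01,
    mean_coding_length: Optional[float] = None,
    stop_exit_fraction: Optional[float] = None,
) -> HMMParameters:
    """Set the 23 transition probabilities from mean region lengths.

    Self-loops realise geometric length distributions: the intergenic state
    leaves with probability 1/L_IR, introns with 1/L_intron, and interior
    exon states exit to a donor with q = 1/(L_exon - 2) so that the expected
    coding-exon run (acceptor + interior + donor) is L_exon.  The E1 row has
    two exits (donor DSS2 and STOP); STOP takes the fraction
    ``stop_exit_fraction`` of the exit mass, by default the reciprocal of
    the mean coding length in codons, keeping the free parameter count at
    23 transitions + 1 smoothing = 24.  All probability mass starts in IR.
    """
    ml = dict(DEFAULT_MEAN_LENGTHS)
    if mean_lengths:
        ml.update(mean_lengths)
    L_ir, L_in, L_ex = ml["intergenic"], ml["intron"], ml["coding_exon"]
    if min(L_ir, L_in, L_ex) <= 1 or L_ex <= 3:
        raise ValueError(f"mean lengths must exceed 1 (and exon > 3): {ml}")
    if mean_coding_length is None:
        mean_coding_length = ml.get("coding_length", 5.0 * L_ex)
    if stop_exit_fraction is None:
        stop_exit_fraction = 3.0 / mean_coding_length
    s = float(stop_exit_fraction)
    if not (0.0 < s < 1.0):
        raise ValueError(f"stop exit fraction must lie in (0, 1), got {s}")

    q = 1.0 / (L_ex - 2.0)
    A = np.zeros((ab.N_STATES, ab.N_STATES))
    A[ab.IR, ab.IR] = 1.0 - 1.0 / L_ir
    A[ab.IR, ab.START] = 1.0 / L_ir
    A[ab.START, ab.E1] = 1.0
    A[ab.E0, ab.E1] = 1.0 - q
    A[ab.E0, ab.DSS1] = q
    A[ab.E2, ab.E0] = 1.0 - q
    A[ab.E2, ab.DSS0] = q
    A[ab.E1, ab.E2] = 1.0 - q
    A[ab.E1, ab.STOP] = q * s
    A[ab.E1, ab.DSS2] = q * (1.0 - s)
    for i, (dss, intron, acc) in enumerate(
        [(ab.DSS0, ab.I1, ab.ASS1), (ab.DSS1, ab.I2, ab.ASS2), (ab.DSS2, ab.I0, ab.ASS0)]
    ):
        A[dss, intron] = 1.0
    for intron, acc in [(ab.I0, ab.ASS0), (ab.I1, ab.ASS1), (ab.I2, ab.ASS2)]:
        A[intron, intron] = 1.0 - 1.0 / L_in
        A[intron, acc] = 1.0 / L_in
    A[ab.ASS0, ab.E1] = 1.0
    A[ab.ASS1, ab.E2] = 1.0
    A[ab.ASS2, ab.E0] = 1.0
    A[ab.STOP, ab.IR] = 1.0

    init = np.zeros(ab.N_STATES)
    init[ab.IR] = 1.0
    return HMMParameters(
        transition_matrix=A,
        initial_distribution=init,
        emission_smoothing=emission_smoothing,
        mean_lengths=ml,
    )


def sequence_constraint_masks(record: GenomeRecord | str) -> ConstraintMask:
    """Binary state-allowance mask derived from the nucleotide sequence.

    * START only where ``seq[i:i+3] == ATG``;
    * STOP only where ``seq[i-2:i+1]`` is a stop triplet;
    * DSS_j only where ``seq[i+1:i+3] == GT`` (intron begins after the donor);
    * ASS_j only where ``seq[i-2:i] == AG`` (intron ends before the acceptor);
    * E2 and DSS2 (codon position 2 within an exon) forbidden where
      ``seq[i-2:i+1]`` is a stop triplet, which prevents in-frame stop codons
      lying wholly inside an exon (spliced stops are not prevented);
    * an N anywhere in a signal's window disallows that signal state;
    * non-coding states (IR, introns) are never masked.
    """
    seq = record.sequence if isinstance(record, GenomeRecord) else record
    T = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    isA, isC = arr == ord("A"), arr == ord("C")
    isG, isT = arr == ord("G"), arr == ord("T")

    mask = np.ones((T, ab.N_STATES), dtype=np.uint8)
    if T == 0:
        return ConstraintMask(mask)

    def shifted(v: np.ndarray, k: int) -> np.ndarray:
        out = np.zeros(T, dtype=bool)
        if k >= 0:
            out[: T - k or None] = v[k:] if k else v
        else:
            out[-k:] = v[:k]
        return out

    atg = shifted(isA, 0) & shifted(isT, 1) & shifted(isG, 2)
    stop_end = (
        (shifted(isT, -2) & shifted(isA, -1) & shifted(isA, 0))
        | (shifted(isT, -2) & shifted(isA, -1) & shifted(isG, 0))
        | (shifted(isT, -2) & shifted(isG, -1) & shifted(isA, 0))
    )
    donor = shifted(isG, 1) & shifted(isT, 2)
    acceptor = shifted(isA, -2) & shifted(isG, -1)

    mask[:, ab.START] = atg
    mask[:, ab.STOP] = stop_end
    for d in (ab.DSS0, ab.DSS1, ab.DSS2):
        mask[:, d] = donor
    for a in (ab.ASS0, ab.ASS1, ab.ASS2):
        mask[:, a] = acceptor
    # no in-frame stops wholly within an exon
    mask[:, ab.E2] &= ~stop_end
    mask[:, ab.DSS2] &= ~stop_end
    return ConstraintMask(mask)


def emission_likelihoods(
    X: ClassProbMatrix | np.ndarray,
    mask: ConstraintMask | np.ndarray | None,
    epsilon: float,
) -> np.ndarray:
    """``mask * ((1-ε)·X + ε/15)``; rows are not renormalised."""
    if not (0.0 <= epsilon < 1.0):
        raise ValueError(f"emission smoothing must lie in [0, 1), got {epsilon}")
    P = X.probabilities if isinstance(X, ClassProbMatrix) else np.asarray(X, dtype=np.float64)
    lik = (1.0 - epsilon) * P + epsilon / ab.N_STATES
    if mask is not None:
        m = mask.mask if isinstance(mask, ConstraintMask) else np.asarray(mask)
        lik = lik * m
    return lik


def _boundary_vectors(
    params: HMMParameters, boundary: str
) -> tuple[np.ndarray, np.ndarray]:
    """Initial distribution and final-state allowance for a decode.

    ``"ir"``: paths start and end in IR (whole records).  ``"free"``: any
    state may start/end (tile-internal windows).  A 2-tuple like
    ``("ir", "free")`` sets the two ends independently.
    """
    if isinstance(boundary, (tuple, list)):
        left, right = boundary
    else:
        left = right = boundary
    if left == "ir":
        init = params.initial_distribution
    elif left == "free":
        init = np.full(ab.N_STATES, 1.0 / ab.N_STATES)
    else:
        raise ValueError(f"unknown boundary condition {left!r}")
    if right == "ir":
        final = np.zeros(ab.N_STATES, dtype=bool)
        final[ab.IR] = True
    elif right == "free":
        final = np.ones(ab.N_STATES, dtype=bool)
    else:
        raise ValueError(f"unknown boundary condition {right!r}")
    return init, final


def forward_backward(
    likelihoods: np.ndarray,
    params: HMMParameters,
    boundary: str = "ir",
) -> ClassProbMatrix:
    """Posterior state probabilities P(state_i = q | inputs).

    Computed with per-step scaling; rows sum to 1.  Raises
    :class:`DecodingError` naming the first position where the mask admits
    no continuation.
    """
    E = np.ascontiguousarray(likelihoods, dtype=np.float64)
    init, final = _boundary_vectors(params, boundary)
    gamma, ll, dead = forward_backward_kernel(E, params.transition_matrix, init, final)
    if dead >= 0:
        raise DecodingError(dead)
    return ClassProbMatrix(gamma)


def forward_log_likelihood(
    likelihoods: np.ndarray, params: HMMParameters, boundary: str = "ir"
) -> float:
    """Log of the total path probability (scaled forward recursion)."""
    E = np.asarray(likelihoods, dtype=np.float64)
    init, final = _boundary_vectors(params, boundary)
    A = params.transition_matrix
    alpha = init * E[0]
    ll = 0.0
    for t in range(E.shape[0]):
        if t > 0:
            alpha = (alpha @ A) * E[t]
        c = alpha.sum()
        if c <= 0.0:
            raise DecodingError(t)
        ll += np.log(c)
        alpha = alpha / c
    tail = alpha[final].sum()
    if tail <= 0.0:
        raise DecodingError(E.shape[0] - 1)
    return float(ll + np.log(tail))
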