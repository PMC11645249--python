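"""The fixed 15-state alphabet of gene-structure labels and its transition grammar.

Every base of a genome gets exactly one of 15 labels:

* ``IR`` — intergenic region.
* ``I0, I1, I2`` — intron positions, indexed by the codon position (reading
  frame) of the *next* coding base after the intron.
* ``E0, E1, E2`` — interior coding-exon positions, indexed by the codon
  position of the base itself (0 = first base of a codon).
* ``ASS0..2`` / ``DSS0..2`` — the first / last base of a coding exon that is
  preceded / followed by an intron (acceptor / donor splice-site border
  states), indexed like ``E``.
* ``START`` — the first base of the start codon (the ``A`` of ``ATG``).
* ``STOP`` — the last base of the stop codon.

Eleven states are coding (``E*``, ``ASS*``, ``DSS*``, ``START``, ``STOP``),
four are non-coding (``IR``, ``I*``).  The directed transition graph between
labels has exactly 23 edges and defines the regular grammar of admissible
gene structures: genes begin ``START → E1``, codon positions cycle
``... → E2 → E0 → E1 → ...``, introns interrupt the cycle between a donor
``DSS_i`` and an acceptor ``ASS_{(i+1) mod 3}`` while remembering the frame,
and genes end ``E1 → STOP → IR``.  This module is the single source of truth
for state indices and edges; the HMM, the losses, the label codec and the
network all import it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "StateAlphabet",
    "STATE_NAMES",
    "ALPHABET",
    "N_STATES",
    "IR",
    "I0",
    "I1",
    "I2",
    "E0",
    "E1",
    "E2",
    "ASS0",
    "ASS1",
    "ASS2",
    "DSS0",
    "DSS1",
    "DSS2",
    "START",
    "STOP",
    "EDGES",
    "N_EDGES",
]

STATE_NAMES: Tuple[str, ...] = (
    "IR",
    "I0",
    "I1",
    "I2",
    "E0",
    "E1",
    "E2",
    "ASS0",
    "ASS1",
    "ASS2",
    "DSS0",
    "DSS1",
    "DSS2",
    "START",
    "STOP",
)

N_STATES = len(STATE_NAMES)

(IR, I0, I1, I2, E0, E1, E2, ASS0, ASS1, ASS2, DSS0, DSS1, DSS2, START, STOP) = range(
    N_STATES
)

E = (E0, E1, E2)
I = (I0, I1, I2)  # noqa: E741 - domain name
ASS = (ASS0, ASS1, ASS2)
DSS = (DSS0, DSS1, DSS2)

#: The 23 admissible label transitions.  Intron states carry the codon
#: position of the next coding base, so a donor in frame i hands over to
#: intron I_{(i+1) mod 3}, which hands over to acceptor ASS_{(i+1) mod 3},
#: whose successor exon base is in frame (i+2) mod 3.
EDGES: Tuple[Tuple[int, int], ...] = (
    (IR, IR),
    (IR, START),
    (START, E1),
    (E0, E1),
    (E1, E2),
    (E2, E0),
    (E2, DSS0),
    (E0, DSS1),
    (E1, DSS2),
    (DSS0, I1),
    (DSS1, I2),
    (DSS2, I0),
    (I0, I0),
    (I1, I1),
    (I2, I2),
    (I0, ASS0),
    (I1, ASS1),
    (I2, ASS2),
    (ASS0, E1),
    (ASS1, E2),
    (ASS2, E0),
    (E1, STOP),
    (STOP, IR),
)

N_EDGES = len(EDGES)


@dataclass(frozen=True)
class StateAlphabet:
    """The ordered 15-state label set shared by all components.

    Attributes
    ----------
    states
        State names in the fixed index order.
    exon_class_indices
        Indices of the 11 coding states (``E*``, ``ASS*``, ``DSS*``,
        ``START``, ``STOP``).
    noncoding_indices
        Indices of the 4 non-coding states (``IR``, ``I*``).
    """

    states: Tuple[str, ...] = STATE_NAMES
    exon_class_indices: Tuple[int, ...] = (
        E0,
        E1,
        E2,
        ASS0,
        ASS1,
        ASS2,
        DSS0,
        DSS1,
        DSS2,
        START,
        STOP,
    )
    noncoding_indices: Tuple[int, ...] = (IR, I0, I1, I2)
    edges: Tuple[Tuple[int, int], ...] = EDGES

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, name: str) -> int:
        return self.states.index(name)

    def adjacency(self) -> np.ndarray:
        """Boolean 15x15 matrix with ``True`` on the 23 allowed edges."""
        adj = np.zeros((self.n_states, self.n_states), dtype=bool)
        for a, b in self.edges:
            adj[a, b] = True
        return adj

    #: codon position carried by each state, -1 for states without one (IR).
    #: Intron states carry the frame of the next coding base.
    def codon_position(self, state: int) -> int:
        table = {
            E0: 0,
            E1: 1,
            E2: 2,
            ASS0: 0,
            ASS1: 1,
            ASS2: 2,
            DSS0: 0,
            DSS1: 1,
            DSS2: 2,
            START: 0,
            STOP: 2,
            I0: 0,
            I1: 1,
            I2: 2,
        }
        return table.get(state, -1)


#: Module-level singleton; the alphabet is fixed, so most callers use this.
ALPHABET = StateAlphabet()


def exon_state_for_frame(frame: int) -> int:
    return E[frame % 3]


def donor_state_for_frame(frame: int) -> int:
    return DSS[frame % 3]


def acceptor_state_for_frame(frame: int) -> int:
    return ASS[frame % 3]


def intron_state_for_frame(frame: int) -> int:
    return I[frame % 3]
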