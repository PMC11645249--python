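"""Independent brute-force references used by the test suite.

Everything here enumerates paths over the 23-edge transition graph
directly, with no shared code with the package's dynamic programs.
"""

from __future__ import annotations

import numpy as np

from locusnet.alphabet import EDGES, IR, N_STATES

SUCCESSORS = {p: [q for (pp, q) in EDGES if pp == p] for p in range(N_STATES)}


def enumerate_paths(E, A, init, final_allowed):
    """Exhaustive path sum and max over the edge graph.

    Returns (best_score, best_path, posteriors, log_likelihood); the best
    path is the first one found in lexicographic (left-to-right,
    lowest-state-first) enumeration among score ties.
    """
    T = E.shape[0]
    best = {"score": -np.inf, "path": None}
    post = np.zeros((T, N_STATES))
    total = [0.0]

    def rec(t, q, p_lin, path):
        p_lin = p_lin * E[t, q]
        if p_lin == 0.0:
            return
        path.append(q)
        if t == T - 1:
            if final_allowed[q]:
                logp = np.log(p_lin)
                if logp > best["score"]:
                    best["score"], best["path"] = logp, list(path)
                total[0] += p_lin
                for tt, qq in enumerate(path):
                    post[tt, qq] += p_lin
        else:
            for q2 in SUCCESSORS[q]:
                if A[q, q2] > 0:
                    rec(t + 1, q2, p_lin * A[q, q2], path)
        path.pop()

    for q in range(N_STATES):
        if init[q] > 0:
            rec(0, q, init[q], [])
    if total[0] > 0:
        post = post / total[0]
        ll = float(np.log(total[0]))
    else:
        ll = -np.inf
    return best["score"], best["path"], post, ll


def path_score(labels, E, A, init):
    """Log-score of one concrete path (emissions + transitions)."""
    with np.errstate(divide="ignore"):
        s = np.log(init[labels[0]]) + np.log(E[0, labels[0]])
        for t in range(1, len(labels)):
            s += np.log(A[labels[t - 1], labels[t]]) + np.log(E[t, labels[t]])
    return float(s)


def adjacency_valid(labels) -> bool:
    """Brute-force membership test of every adjacent pair in the edge set."""
    return all((int(a), int(b)) in set(EDGES) for a, b in zip(labels[:-1], labels[1:]))


def random_masked_emissions(rng, T, ir_always=True):
    """Random positive emissions with a random binary mask (IR kept open)."""
    E = rng.random((T, N_STATES)) + 1e-3
    mask = rng.random((T, N_STATES)) < 0.8
    if ir_always:
        mask[:, IR] = True
    return E * mask
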