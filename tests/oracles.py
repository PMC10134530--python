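"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package internals: the pruning
oracle enumerates complete state assignments over every tree node, and the
HMM oracles enumerate every configuration path through the chain.
"""

from __future__ import annotations

import itertools
from typing import List, Sequence, Tuple

import numpy as np

# state order U, F, S1, S2 — observation indicator vectors per tip
TIP_OK = {
    "BOTH": np.array([1.0, 1.0, 0.0, 0.0]),
    "ONLY_SUB1": np.array([0.0, 0.0, 1.0, 0.0]),
    "ONLY_SUB2": np.array([0.0, 0.0, 0.0, 1.0]),
    "MISSING": np.array([1.0, 1.0, 1.0, 1.0]),
}

PRESENCE_TO_OBS = {
    0: ("MISSING", "MISSING"),
    1: ("ONLY_SUB1", "ONLY_SUB2"),
    2: ("ONLY_SUB2", "ONLY_SUB1"),
    3: ("BOTH", "BOTH"),
}


def loss_transition(phi: float, eps: float, t: float) -> np.ndarray:
    """Reference transition matrix via the generic matrix exponential."""
    from scipy.linalg import expm

    q = np.zeros((4, 4))
    q[0, 1], q[0, 2], q[0, 3] = phi, 1.0, eps
    q[0, 0] = -(phi + 1.0 + eps)
    return expm(q * t)


def brute_force_pillar_likelihood(
    pattern: Sequence[int],
    tree,
    phi: float,
    eps: float,
    config_bits: int,
) -> float:
    """Sum over all 4^n_nodes state assignments of the joint probability.

    ``pattern`` holds per-tip presence classes in tree tip order;
    ``config_bits`` maps tip i to SWAPPED when bit i is set.
    """
    trans = {node: loss_transition(phi, eps, float(t)) for node, t in enumerate(tree.lengths)}
    nodes = list(range(tree.n_nodes))
    tip_of_node = {node: i for i, node in enumerate(tree.tip_nodes)}
    total = 0.0
    for states in itertools.product(range(4), repeat=len(nodes)):
        prob = trans[tree.root][0, states[tree.root]]  # stem from U
        for node in nodes:
            if node == tree.root:
                continue
            prob *= trans[node][states[tree.parent[node]], states[node]]
        if prob == 0.0:
            continue
        for node in tree.tip_nodes:
            g = tip_of_node[node]
            swapped = (config_bits >> g) & 1
            obs = PRESENCE_TO_OBS[int(pattern[g])][swapped]
            prob *= TIP_OK[obs][states[node]]
        total += prob
    return total


def _path_iter(n_pillars: int, n_cfg: int):
    return itertools.product(range(n_cfg), repeat=n_pillars)


def _path_log_prob(
    path: Tuple[int, ...],
    log_e: np.ndarray,
    s: float,
    n_genomes: int,
    block_of: Sequence[int],
) -> float:
    n_cfg = 1 << n_genomes
    lp = 0.0
    for t, c in enumerate(path):
        if t == 0 or block_of[t] != block_of[t - 1]:
            lp += -np.log(n_cfg)
        else:
            flips = bin(path[t - 1] ^ c).count("1")
            if flips:
                if s == 0.0:
                    return -np.inf
                lp += flips * np.log(s)
            lp += (n_genomes - flips) * np.log1p(-s)
        lp += log_e[t, c]
    return lp


def exhaustive_posteriors(
    log_e: np.ndarray, s: float, n_genomes: int, block_of: Sequence[int]
) -> Tuple[np.ndarray, float]:
    """Posterior per pillar per config by summing every configuration path."""
    n_pillars, n_cfg = log_e.shape
    joint = np.zeros((n_pillars, n_cfg))
    total = 0.0
    for path in _path_iter(n_pillars, n_cfg):
        p = np.exp(_path_log_prob(path, log_e, s, n_genomes, block_of))
        total += p
        for t, c in enumerate(path):
            joint[t, c] += p
    return joint / total, float(np.log(total))


def exhaustive_viterbi(
    log_e: np.ndarray, s: float, n_genomes: int, block_of: Sequence[int]
) -> Tuple[Tuple[int, ...], float]:
    """Best path by enumeration; ties keep the lexicographically first path."""
    best_path, best_score = None, -np.inf
    for path in _path_iter(log_e.shape[0], log_e.shape[1]):
        score = _path_log_prob(path, log_e, s, n_genomes, block_of)
        if score > best_score + 1e-12:
            best_path, best_score = path, score
    return best_path, float(best_score)
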