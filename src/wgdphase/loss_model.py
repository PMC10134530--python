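"""Four-state Markov model of duplicate-gene fate after polyploidy.

At the WGD event every ancestral locus starts as an undifferentiated
duplicate pair (state U).  Along each branch of the species tree the pair can
resolve, irreversibly, into one of three absorbing fates:

* F  — both copies fixed (preserved duplicates),
* S1 — the copy on subgenome 2 is lost (subgenome 1 survives),
* S2 — the copy on subgenome 1 is lost (subgenome 2 survives).

Rates out of U: phi to F, 1 to S1 (the scale convention that makes branch
lengths identifiable), and epsilon to S2.  With 0 <= epsilon < 1 losses
preferentially remove subgenome-2 copies, i.e. subgenome 1 is the favoured
("less fractionated") parental genome — the biased-fractionation parameter.

The per-pillar likelihood of a presence/absence pattern under a given
orthology configuration is computed with Felsenstein pruning over this model,
with the root (the event itself) in state U and the stem branch applied
before the first divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import (
    PRESENCE_BOTH,
    PRESENCE_NONE,
    PRESENCE_ONLY_A,
    PRESENCE_ONLY_B,
    OrthologyConfiguration,
    Pillar,
    SpeciesTree,
)
from .errors import ValidationError

# State order (fixed): U, F, S1, S2
STATE_U, STATE_F, STATE_S1, STATE_S2 = 0, 1, 2, 3
STATE_NAMES = ("U", "F", "S1", "S2")

# Tip observation codes
OBS_BOTH, OBS_ONLY_SUB1, OBS_ONLY_SUB2, OBS_MISSING = 0, 1, 2, 3
OBS_NAMES = ("BOTH", "ONLY_SUB1", "ONLY_SUB2", "MISSING")

# Conditional likelihood of the observation given each state at the tip.
# BOTH is compatible with U or F; a single survivor pins down the subgenome;
# a genome absent from the pillar is missing data, not evidence of loss.
_TIP_PARTIALS = np.array(
    [
        [1.0, 1.0, 0.0, 0.0],  # BOTH
        [0.0, 0.0, 1.0, 0.0],  # ONLY_SUB1
        [0.0, 0.0, 0.0, 1.0],  # ONLY_SUB2
        [1.0, 1.0, 1.0, 1.0],  # MISSING
    ]
)

# observation = _OBS_TABLE[presence_class, swapped_bit]
_OBS_TABLE = np.empty((4, 2), dtype=np.int8)
_OBS_TABLE[PRESENCE_NONE] = (OBS_MISSING, OBS_MISSING)
_OBS_TABLE[PRESENCE_ONLY_A] = (OBS_ONLY_SUB1, OBS_ONLY_SUB2)
_OBS_TABLE[PRESENCE_ONLY_B] = (OBS_ONLY_SUB2, OBS_ONLY_SUB1)
_OBS_TABLE[PRESENCE_BOTH] = (OBS_BOTH, OBS_BOTH)


@dataclass(frozen=True)
class LossModel:
    """Duplicate-fate CTMC with retention rate phi and loss bias epsilon."""

    phi: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValidationError("phi must be >= 0")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValidationError("epsilon must be in [0, 1]")

    @property
    def exit_rate(self) -> float:
        return self.phi + 1.0 + self.epsilon

    def rate_matrix(self) -> np.ndarray:
        q = np.zeros((4, 4))
        q[STATE_U, STATE_F] = self.phi
        q[STATE_U, STATE_S1] = 1.0
        q[STATE_U, STATE_S2] = self.epsilon
        q[STATE_U, STATE_U] = -self.exit_rate
        return q

    def transition_matrix(self, t: float) -> np.ndarray:
        """Closed-form P(t); absorbing rows are identity."""
        if t < 0:
            raise ValidationError("t must be >= 0")
        r = self.exit_rate
        decay = np.exp(-r * t)
        p = np.eye(4)
        p[STATE_U, STATE_U] = decay
        absorbed = 1.0 - decay
        if r > 0:
            p[STATE_U, STATE_F] = self.phi / r * absorbed
            p[STATE_U, STATE_S1] = 1.0 / r * absorbed
            p[STATE_U, STATE_S2] = self.epsilon / r * absorbed
        return p


def tip_partial(obs: int) -> np.ndarray:
    """Length-4 conditional likelihood vector for a tip observation."""
    return _TIP_PARTIALS[obs].copy()


def observation(presence_class: int, swapped: bool) -> int:
    """Map a pillar's per-genome presence class through a configuration."""
    return int(_OBS_TABLE[presence_class, int(swapped)])


def pattern_log_likelihoods(
    patterns: np.ndarray,
    tree: SpeciesTree,
    model: LossModel,
    config_bits: Sequence[int],
) -> np.ndarray:
    """Pruning log-likelihoods for many patterns under many configurations.

    Parameters
    ----------
    patterns
        (P, n) array of presence classes, genome columns in tree tip order.
    config_bits
        Configuration bitmasks (bit i set = genome i SWAPPED).

    Returns
    -------
    (P, C) array of log-likelihoods.
    """
    patterns = np.asarray(patterns, dtype=np.int8)
    if patterns.ndim != 2 or patterns.shape[1] != tree.n_tips:
        raise ValidationError("patterns must be (n_patterns, n_genomes)")
    bits = np.asarray(config_bits, dtype=np.int64)
    n_pat, n_gen = patterns.shape
    n_cfg = bits.shape[0]

    trans = [model.transition_matrix(float(t)) for t in tree.lengths]

    # swapped-bit per (config, genome)
    swapped = ((bits[:, None] >> np.arange(n_gen)[None, :]) & 1).astype(np.int8)

    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros((n_pat, n_cfg))
    tip_of_node = {node: i for i, node in enumerate(tree.tip_nodes)}
    for node in tree.postorder:
        if tree.is_tip(node):
            g = tip_of_node[node]
            obs = _OBS_TABLE[patterns[:, g][:, None], swapped[None, :, g]]
            partials[node] = _TIP_PARTIALS[obs]
        else:
            acc = np.ones((n_pat, n_cfg, 4))
            for child in tree.children[node]:
                acc *= partials.pop(child) @ trans[child].T
            scale = acc.max(axis=-1)
            nz = scale > 0
            acc[nz] /= scale[nz, None]
            logs = np.full(scale.shape, -np.inf)
            np.log(scale, out=logs, where=nz)
            log_scale += logs
            partials[node] = acc

    root = tree.root
    root_partial = partials[root]
    # stem branch from the U-state event to the first divergence
    lik = root_partial @ trans[root][STATE_U]
    with np.errstate(divide="ignore"):
        return np.log(lik) + log_scale


def pillar_likelihood(
    pillar: Pillar,
    config: OrthologyConfiguration,
    tree: SpeciesTree,
    model: LossModel,
) -> float:
    """Likelihood of one pillar's presence/absence data under one configuration."""
    if set(config.genomes) != set(tree.tip_names):
        raise ValidationError("configuration genomes do not match tree tips")
    for g in pillar.slots:
        if g not in tree.tip_names:
            raise ValidationError(f"pillar genome {g} not in tree")
    pattern = np.array([[pillar.presence(g) for g in tree.tip_names]], dtype=np.int8)
    # re-map configuration bits into tree tip order
    bits = 0
    for i, g in enumerate(tree.tip_names):
        if config.is_swapped(config.genomes.index(g)):
            bits |= 1 << i
    log_lik = pattern_log_likelihoods(pattern, tree, model, [bits])[0, 0]
    return float(np.exp(log_lik))
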