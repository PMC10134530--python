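"""Hidden Markov model over pillars for orthology-configuration tracking.

The hidden state at each pillar is one of the 2^n orthology configurations
(which extant track corresponds to which parental subgenome, per genome).
Emissions are the pruning likelihoods of the pillar's presence/absence data
under the duplicate-loss model; transitions model tracking switches — per
genome, per adjacent pillar pair, the track->subgenome assignment flips with
probability s (a rearrangement breaking synteny), independently across
genomes.  The chain resets at ancestral-block boundaries, where tracking
cannot persist.

Posterior decoding (forward-backward) yields, per pillar, the probability of
every configuration conditional on the entire pillar set; the reported
confidence is the posterior mass of the Viterbi configuration at that pillar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .datamodel import OrthologyConfiguration, Pillar, PillarSet, SpeciesTree
from .errors import CapabilityError, ValidationError
from .loss_model import LossModel, pattern_log_likelihoods

MAX_GENOMES = 12

# Pillar categories from the decoded configuration
DUPLICATED = "DUPLICATED"
SINGLE_SUB1 = "SINGLE_SUB1"
SINGLE_SUB2 = "SINGLE_SUB2"
MIXED = "MIXED"
RECIPROCAL_LOSS = "RECIPROCAL_LOSS"


def enumerate_configurations(genomes: Sequence[str]) -> List[OrthologyConfiguration]:
    """All 2^n orthology configurations in deterministic binary order.

    Configuration c has genome i SWAPPED iff bit i of c is set; genome order
    follows the species-tree tip order.
    """
    genomes = tuple(genomes)
    n = len(genomes)
    if not 1 <= n <= MAX_GENOMES:
        raise CapabilityError(
            f"genome count {n} outside supported range 1..{MAX_GENOMES}"
        )
    if n > 8:
        warnings.warn(
            f"{n} genomes -> {1 << n} configurations; inference will be slow",
            stacklevel=2,
        )
    return [OrthologyConfiguration(genomes, bits) for bits in range(1 << n)]


@dataclass
class HMMSpec:
    """State space and transition structure of the tracking HMM."""

    genomes: Tuple[str, ...]
    switch_prob: float
    block_bounds: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.switch_prob < 0.5:
            raise ValidationError("switch probability must be in [0, 0.5)")
        self.genomes = tuple(self.genomes)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def n_configs(self) -> int:
        return 1 << self.n_genomes

    @property
    def configs(self) -> List[OrthologyConfiguration]:
        return enumerate_configurations(self.genomes)

    def transition_kernel(self) -> np.ndarray:
        """(2^n, 2^n) matrix; entry [c, c'] = prod_g s^[flip] (1-s)^[no flip]."""
        n = self.n_genomes
        idx = np.arange(1 << n)
        xor = idx[:, None] ^ idx[None, :]
        flips = np.zeros_like(xor)
        for g in range(n):
            flips += (xor >> g) & 1
        s = self.switch_prob
        return (s ** flips) * ((1.0 - s) ** (n - flips))


@dataclass
class PosteriorTable:
    """Per-pillar posterior over configurations plus the Viterbi decode."""

    genomes: Tuple[str, ...]
    posteriors: np.ndarray  # (P, 2^n), rows sum to 1
    viterbi_path: np.ndarray  # (P,) config indices
    log_likelihood: float

    @property
    def n_pillars(self) -> int:
        return self.posteriors.shape[0]

    @property
    def confidence(self) -> np.ndarray:
        """Posterior mass of the Viterbi configuration at each pillar."""
        return self.posteriors[np.arange(self.n_pillars), self.viterbi_path]

    def viterbi_config(self, pillar_index: int) -> OrthologyConfiguration:
        return OrthologyConfiguration(
            self.genomes, int(self.viterbi_path[pillar_index])
        )


def emission_matrix(
    pillars: PillarSet, tree: SpeciesTree, model: LossModel
) -> np.ndarray:
    """(n_pillars, 2^n) log-likelihood table, configs in binary order.

    Pillars sharing a presence/absence pattern share a row computation: the
    pruning likelihood depends on the pattern only.
    """
    if set(pillars.genomes) != set(tree.tip_names):
        raise ValidationError("pillar genomes do not match tree tips")
    order = [pillars.genomes.index(g) for g in tree.tip_names]
    patterns = pillars.presence_matrix()[:, order]
    uniq, inverse = np.unique(patterns, axis=0, return_inverse=True)
    n = tree.n_tips
    # config bits are defined over pillars.genomes order; re-map to tip order
    bits = np.arange(1 << n)
    tip_bits = np.zeros_like(bits)
    for tip_i, gen_i in enumerate(order):
        tip_bits |= ((bits >> gen_i) & 1) << tip_i
    log_lik = pattern_log_likelihoods(uniq, tree, model, tip_bits)
    return log_lik[inverse]


def forward_backward(
    log_emissions: np.ndarray, hmm: HMMSpec
) -> Tuple[np.ndarray, float]:
    """Posterior configuration probabilities per pillar and total log-likelihood.

    The initial distribution is uniform over configurations at every block
    start, and blocks are independent (the chain resets at block boundaries).
    """
    n_pillars, n_cfg = log_emissions.shape
    if n_cfg != hmm.n_configs:
        raise ValidationError("emission table width does not match state space")
    if n_pillars < 1:
        raise ValidationError("need at least one pillar")
    kernel = hmm.transition_kernel()
    post = np.empty_like(log_emissions)
    total = 0.0
    for start, end in hmm.block_bounds:
        p, ll = _forward_backward_block(log_emissions[start:end], kernel)
        post[start:end] = p
        total += ll
    return post, total


def _forward_backward_block(
    log_e: np.ndarray, kernel: np.ndarray
) -> Tuple[np.ndarray, float]:
    t_len, n_cfg = log_e.shape
    offsets = log_e.max(axis=1)
    if not np.isfinite(offsets).all():
        # some pillar is impossible under every configuration (emission
        # underflow at extreme parameters): zero total likelihood
        return np.full_like(log_e, 1.0 / n_cfg), -np.inf
    e = np.exp(log_e - offsets[:, None])
    alpha = np.empty_like(e)
    norms = np.empty(t_len)
    a = e[0] / n_cfg
    norms[0] = a.sum()
    alpha[0] = a / norms[0]
    for t in range(1, t_len):
        a = (alpha[t - 1] @ kernel) * e[t]
        norms[t] = a.sum()
        if norms[t] <= 0.0:  # impossible path set (e.g. s = 0 with a switch)
            return np.full_like(log_e, 1.0 / n_cfg), -np.inf
        alpha[t] = a / norms[t]
    beta = np.empty_like(e)
    beta[-1] = 1.0
    for t in range(t_len - 2, -1, -1):
        v = kernel @ (e[t + 1] * beta[t + 1]) / norms[t + 1]
        # beta enters the posterior only up to a per-pillar constant, so it
        # can be rescaled freely to dodge overflow on near-impossible chains
        vmax = v.max()
        beta[t] = v / vmax if vmax > 0 else 1.0 / n_cfg
    post = alpha * beta
    sums = post.sum(axis=1, keepdims=True)
    # at extreme parameters alpha and beta can end up with disjoint support;
    # fall back to a uniform row rather than emitting NaNs
    ok = np.isfinite(sums[:, 0]) & (sums[:, 0] > 0.0)
    post[ok] /= sums[ok]
    post[~ok] = 1.0 / n_cfg
    log_lik = float(np.log(norms).sum() + offsets.sum())
    return post, log_lik


def viterbi(log_emissions: np.ndarray, hmm: HMMSpec) -> np.ndarray:
    """Most probable configuration path; ties break to the smallest index."""
    n_pillars, n_cfg = log_emissions.shape
    if n_cfg != hmm.n_configs:
        raise ValidationError("emission table width does not match state space")
    with np.errstate(divide="ignore"):
        log_k = np.log(hmm.transition_kernel())
    path = np.empty(n_pillars, dtype=np.int64)
    log_init = -np.log(n_cfg)
    for start, end in hmm.block_bounds:
        log_e = log_emissions[start:end]
        t_len = end - start
        delta = log_init + log_e[0]
        back = np.empty((t_len, n_cfg), dtype=np.int64)
        for t in range(1, t_len):
            scores = delta[:, None] + log_k  # [prev, cur]
            back[t] = np.argmax(scores, axis=0)  # first max = smallest index
            delta = scores[back[t], np.arange(n_cfg)] + log_e[t]
        state = int(np.argmax(delta))
        for t in range(t_len - 1, -1, -1):
            path[start + t] = state
            if t > 0:
                state = int(back[t, state])
    return path


def decode(
    pillars: PillarSet,
    tree: SpeciesTree,
    model: LossModel,
    switch_prob: float,
) -> PosteriorTable:
    """Full posterior decoding of a pillar set: emissions + FB + Viterbi."""
    hmm = HMMSpec(
        genomes=pillars.genomes,
        switch_prob=switch_prob,
        block_bounds=pillars.block_bounds(),
    )
    log_e = emission_matrix(pillars, tree, model)
    post, log_lik = forward_backward(log_e, hmm)
    path = viterbi(log_e, hmm)
    return PosteriorTable(
        genomes=pillars.genomes,
        posteriors=post,
        viterbi_path=path,
        log_likelihood=log_lik,
    )


def classify_pillar(pillar: Pillar, config: OrthologyConfiguration) -> str:
    """Categorize a pillar given its decoded configuration.

    DUPLICATED: every present genome retains both copies.  SINGLE_SUB1/2: all
    present genomes are single-copy on that subgenome.  RECIPROCAL_LOSS: all
    single-copy but both subgenomes represented (the genes are paralogs, not
    orthologs).  MIXED: anything else.
    """
    subgenomes = set()
    any_both = False
    any_single = False
    for i, g in enumerate(config.genomes):
        a, b = pillar.slots.get(g, (None, None))
        present = (a is not None) + (b is not None)
        if present == 0:
            continue
        if present == 2:
            any_both = True
        else:
            any_single = True
            on_a = a is not None
            swapped = config.is_swapped(i)
            subgenomes.add(1 if on_a != swapped else 2)
    if any_both and not any_single:
        return DUPLICATED
    if any_single and not any_both:
        if subgenomes == {1}:
            return SINGLE_SUB1
        if subgenomes == {2}:
            return SINGLE_SUB2
        return RECIPROCAL_LOSS
    return MIXED
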