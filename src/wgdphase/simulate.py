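"""Forward simulator of post-polyploidy gene content with known ground truth.

Each pillar evolves independently down the species tree under the four-state
duplicate-fate model: the locus starts undifferentiated (U) at the WGD event,
runs along the stem, and resolves toward F (retained duplicate), S1 or S2
(single survivor on subgenome 1 / 2) on each branch.  Independently, each
genome carries a track-labeling chain along the pillar order: with
probability s per adjacent pillar the mapping of its two physical tracks to
the two subgenomes flips (a synteny-breaking rearrangement); the chain
restarts with a fair coin at each ancestral-block boundary.

Surviving genes are placed into track slots according to the true labeling,
gene-order tables and dummy in-frame CDS are emitted, and the full truth
(fate state and track assignment per pillar per genome) is kept so that
downstream inference can be scored.

Limitations mirror the model itself: no tandem duplication, no single-gene
translocation, no pillar-order error, and losses independent among pillars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .datamodel import Gene, Pillar, PillarSet, SpeciesTree
from .errors import ValidationError
from .fit import PHI_BOUNDS, S_BOUNDS
from .hmm import PosteriorTable
from .loss_model import STATE_F, STATE_S1, STATE_S2, STATE_U, LossModel

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic dataset."""

    tree: SpeciesTree
    n_pillars: int = 1000
    n_blocks: int = 5
    phi: float = 0.5
    epsilon: float = 0.8
    s: float = 0.02
    seed: int = 0
    fraction_missing: float = 0.0

    def __post_init__(self) -> None:
        if not self.n_pillars >= self.n_blocks >= 1:
            raise ValidationError("need n_pillars >= n_blocks >= 1")
        if not PHI_BOUNDS[0] <= self.phi <= PHI_BOUNDS[1] and self.phi != 0.0:
            raise ValidationError("phi outside fit bounds")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValidationError("epsilon must be in [0, 1]")
        if not S_BOUNDS[0] <= self.s <= S_BOUNDS[1]:
            raise ValidationError("s outside fit bounds")
        if not 0.0 <= self.fraction_missing < 1.0:
            raise ValidationError("fraction_missing must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth per pillar per genome, plus the generating parameters."""

    genomes: Tuple[str, ...]
    states: np.ndarray  # (P, n) tip fate states (U/F/S1/S2)
    swapped: np.ndarray  # (P, n) bool, True = track assignment SWAPPED
    missing: np.ndarray  # (P, n) bool, genome removed from the pillar
    config: SimulationConfig

    def true_config_bits(self) -> np.ndarray:
        """(P,) true configuration bitmask per pillar (genome order bits)."""
        n = len(self.genomes)
        return (self.swapped.astype(np.int64) << np.arange(n)).sum(axis=1)


@dataclass
class SimulationResult:
    pillars: PillarSet
    tree: SpeciesTree
    truth: SimulationTruth
    gene_orders: Dict[str, List[Gene]]
    cds: Dict[str, str]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate a pillar set, gene orders, CDS and truth from the config."""
    tree = config.tree
    rng = np.random.default_rng(config.seed)
    n_pil = config.n_pillars
    n_gen = tree.n_tips
    model = LossModel(phi=config.phi, epsilon=config.epsilon)

    # --- evolve fate states down the tree, vectorized over pillars ---------
    states: Dict[int, np.ndarray] = {}
    preorder = tree.postorder[::-1]
    for node in preorder:
        if node == tree.root:
            start = np.full(n_pil, STATE_U, dtype=np.int8)
        else:
            start = states[tree.parent[node]]
        trans = model.transition_matrix(float(tree.lengths[node]))
        states[node] = _evolve(start, trans, rng)
    tip_states = np.stack(
        [states[tree.tip_node(g)] for g in tree.tip_names], axis=1
    )  # (P, n)

    # --- block structure ----------------------------------------------------
    block_of = np.minimum(
        (np.arange(n_pil) * config.n_blocks) // n_pil, config.n_blocks - 1
    )
    block_ids = [f"blk{b + 1}" for b in block_of]

    # --- per-genome track-labeling chains ----------------------------------
    swapped = np.empty((n_pil, n_gen), dtype=bool)
    for g in range(n_gen):
        flips = rng.random(n_pil)
        for i in range(n_pil):
            if i == 0 or block_of[i] != block_of[i - 1]:
                swapped[i, g] = flips[i] < 0.5
            else:
                swapped[i, g] = swapped[i - 1, g] ^ (flips[i] < config.s)

    # --- genome removal (missing data) --------------------------------------
    missing = rng.random((n_pil, n_gen)) < config.fraction_missing
    empty = missing.all(axis=1)
    missing[empty, 0] = False  # keep every pillar observable in >=1 genome

    # --- assemble pillars, gene orders, CDS ---------------------------------
    genomes = tuple(tree.tip_names)
    pillars: List[Pillar] = []
    gene_orders: Dict[str, List[Gene]] = {g: [] for g in genomes}
    cds: Dict[str, str] = {}
    positions = {g: {} for g in genomes}  # (chrom) -> running coordinate

    for i in range(n_pil):
        slots: Dict[str, Tuple[Optional[str], Optional[str]]] = {}
        for j, g in enumerate(genomes):
            if missing[i, j]:
                slots[g] = (None, None)
                continue
            state = tip_states[i, j]
            present = {  # subgenome -> gene?
                1: state in (STATE_U, STATE_F, STATE_S1),
                2: state in (STATE_U, STATE_F, STATE_S2),
            }
            track_genes: List[Optional[str]] = [None, None]
            for sub in (1, 2):
                if not present[sub]:
                    continue
                # IDENTITY: sub1 -> track A (0); SWAPPED: sub1 -> track B (1)
                track = (sub - 1) ^ int(swapped[i, j])
                gid = f"{g}_p{i:05d}s{sub}"
                track_genes[track] = gid
            slots[g] = (track_genes[0], track_genes[1])
            for track, gid in enumerate(track_genes):
                if gid is None:
                    continue
                chrom = f"chr_{block_ids[i]}_{'AB'[track]}"
                pos = positions[g].get(chrom, 1)
                gene = Gene(
                    gene_id=gid, genome=g, chromosome=chrom,
                    start=pos, end=pos + 299,
                    strand="+" if rng.random() < 0.5 else "-",
                )
                positions[g][chrom] = pos + 400
                gene_orders[g].append(gene)
                cds[gid] = _random_cds(rng)
        pillars.append(Pillar(index=i, block_id=block_ids[i], slots=slots))

    truth = SimulationTruth(
        genomes=genomes,
        states=tip_states,
        swapped=swapped,
        missing=missing,
        config=config,
    )
    return SimulationResult(
        pillars=PillarSet(pillars=pillars, genomes=genomes),
        tree=tree,
        truth=truth,
        gene_orders=gene_orders,
        cds=cds,
    )


def _evolve(states: np.ndarray, trans: np.ndarray, rng) -> np.ndarray:
    """Sample child states given parent states and a transition matrix."""
    out = states.copy()
    in_u = states == STATE_U  # absorbing states stay put
    n_u = int(in_u.sum())
    if n_u:
        cum = np.cumsum(trans[STATE_U])
        draws = rng.random(n_u)
        out[in_u] = np.searchsorted(cum, draws).astype(np.int8)
    return out


def _random_cds(rng, n_codons: int = 98) -> str:
    # start codon + 98 internal codons + stop = 300 nt
    codons = rng.integers(0, len(_CODONS), size=n_codons)
    return "ATG" + "".join(_CODONS[c] for c in codons) + "TAA"


# ---------------------------------------------------------------------------
# Scoring inference against truth


@dataclass
class AccuracyReport:
    accuracy: float  # exact configuration match per pillar
    accuracy_mod_swap: float  # best of direct and globally complemented path
    mean_confidence: float
    calibration: List[Tuple[float, float, float, int]]
    # (bin_low, bin_high, empirical_accuracy, count)


def score_inference(
    truth: SimulationTruth, posterior: PosteriorTable, n_bins: int = 10
) -> AccuracyReport:
    """Score a decoded pillar set against simulation truth.

    Accuracy is the fraction of pillars whose Viterbi configuration equals
    the true one; the mod-swap variant also accepts the global label
    complement (the two subgenome labelings are unidentifiable when
    epsilon = 1).  The calibration table bins reported confidence and
    compares it with empirical accuracy in each bin.
    """
    if posterior.n_pillars != truth.states.shape[0]:
        raise ValidationError("posterior and truth cover different pillar sets")
    if tuple(posterior.genomes) != tuple(truth.genomes):
        raise ValidationError("posterior and truth genome orders differ")
    true_bits = truth.true_config_bits()
    path = posterior.viterbi_path
    n = len(truth.genomes)
    full = (1 << n) - 1
    correct = path == true_bits
    correct_swap = (path ^ full) == true_bits
    accuracy = float(correct.mean())
    accuracy_mod = float(np.maximum(correct, correct_swap).mean())
    conf = posterior.confidence
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    calibration = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (conf >= lo) & (conf < hi if hi < 1.0 else conf <= hi)
        count = int(mask.sum())
        emp = float(correct[mask].mean()) if count else float("nan")
        calibration.append((float(lo), float(hi), emp, count))
    return AccuracyReport(
        accuracy=accuracy,
        accuracy_mod_swap=accuracy_mod,
        mean_confidence=float(conf.mean()),
        calibration=calibration,
    )
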