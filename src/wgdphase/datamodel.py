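"""Core domain types.

The objects here describe a set of genomes descended from a shared ancient
tetraploidy (whole-genome duplication, WGD):

* :class:`SpeciesTree` — the rooted species phylogeny of the polyploid
  genomes.  The root represents the polyploidy event itself; the stem branch
  between the event and the first speciation is part of the model.  Branch
  lengths are in expected duplicate-resolution events per gene, not
  substitutions.
* :class:`Gene` — one annotated gene with 1-based inclusive coordinates.
* :class:`Pillar` — one ancestral locus: for every genome, two "track" slots
  (the two homeologous regions tiling the ancestral region) each holding a
  surviving gene or nothing.
* :class:`PillarSet` — the ordered list of pillars (ancestral gene order),
  partitioned into contiguous synteny blocks.
* :class:`OrthologyConfiguration` — one of the 2^n ways of assigning every
  genome's two tracks to the two parental subgenomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError

# Per-genome presence classes for a pillar (who survives on which track).
PRESENCE_NONE = 0
PRESENCE_ONLY_A = 1
PRESENCE_ONLY_B = 2
PRESENCE_BOTH = 3

IDENTITY = "IDENTITY"
SWAPPED = "SWAPPED"


@dataclass
class Gene:
    """One gene annotation; coordinates are 1-based inclusive."""

    gene_id: str
    genome: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    common_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class SpeciesTree:
    """Rooted bifurcating species tree with branch lengths.

    Nodes are integer-indexed; every node carries the length of the branch
    above it.  The root's "branch above" is the stem between the polyploidy
    event and the first divergence.  Tips are ordered as encountered
    left-to-right in the source Newick.
    """

    def __init__(
        self,
        parent: Sequence[Optional[int]],
        children: Sequence[Tuple[int, ...]],
        lengths: Sequence[float],
        tip_names: Sequence[str],
        tip_nodes: Sequence[int],
    ) -> None:
        self.parent = list(parent)
        self.children = [tuple(c) for c in children]
        self.lengths = np.asarray(lengths, dtype=float)
        self.tip_names = list(tip_names)
        self.tip_nodes = list(tip_nodes)
        self._validate()
        self.root = next(i for i, p in enumerate(self.parent) if p is None)
        self.postorder = self._postorder()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        n = len(self.parent)
        if not (len(self.children) == len(self.lengths) == n):
            raise ValidationError("inconsistent node arrays")
        if len(self.tip_names) != len(set(self.tip_names)):
            raise ValidationError("tip names are not unique")
        if len(self.tip_names) < 1:
            raise ValidationError("tree must have at least one tip")
        if np.any(self.lengths < 0):
            raise ValidationError("negative branch length")
        roots = [i for i, p in enumerate(self.parent) if p is None]
        if len(roots) != 1:
            raise ValidationError("tree must have exactly one root")
        for i, kids in enumerate(self.children):
            if len(kids) not in (0, 2):
                raise ValidationError(
                    f"node {i} has {len(kids)} children; tree must be bifurcating"
                )

    def _postorder(self) -> List[int]:
        order: List[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    # -- accessors -----------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root_branch_length(self) -> float:
        """Stem length between the WGD event and the first divergence."""
        return float(self.lengths[self.root])

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def tip_node(self, name: str) -> int:
        return self.tip_nodes[self.tip_names.index(name)]

    def with_lengths(self, lengths: Sequence[float]) -> "SpeciesTree":
        """Copy of the tree with every node's branch length replaced."""
        return SpeciesTree(
            self.parent, self.children, lengths, self.tip_names, self.tip_nodes
        )

    def newick(self, include_stem: bool = True) -> str:
        def fmt(node: int) -> str:
            if self.is_tip(node):
                name = self.tip_names[self.tip_nodes.index(node)]
                return f"{name}:{self.lengths[node]:.6g}"
            inner = ",".join(fmt(c) for c in self.children[node])
            if node == self.root:
                stem = f":{self.lengths[node]:.6g}" if include_stem else ""
                return f"({inner}){stem}"
            return f"({inner}):{self.lengths[node]:.6g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return f"SpeciesTree({self.n_tips} tips: {', '.join(self.tip_names)})"


@dataclass
class Pillar:
    """One ancestral locus: per genome, two track slots holding gene ids."""

    index: int
    block_id: str
    slots: Dict[str, Tuple[Optional[str], Optional[str]]]

    def __post_init__(self) -> None:
        n_genes = 0
        for genome, (a, b) in self.slots.items():
            if a is not None and a == b:
                raise ValidationError(
                    f"pillar {self.index}: gene {a} occupies both tracks in {genome}"
                )
            n_genes += (a is not None) + (b is not None)
        if n_genes == 0:
            raise ValidationError(f"pillar {self.index}: no genes in any genome")

    def presence(self, genome: str) -> int:
        """Presence class for a genome: NONE, ONLY_A, ONLY_B, or BOTH."""
        a, b = self.slots.get(genome, (None, None))
        return (PRESENCE_ONLY_A if a is not None else 0) | (
            PRESENCE_ONLY_B if b is not None else 0
        )

    def genes(self, genome: Optional[str] = None) -> List[str]:
        genomes = [genome] if genome is not None else list(self.slots)
        out = []
        for g in genomes:
            for gid in self.slots.get(g, (None, None)):
                if gid is not None:
                    out.append(gid)
        return out

    @property
    def n_genes(self) -> int:
        return len(self.genes())


@dataclass
class PillarSet:
    """Ordered pillars in ancestral gene order, grouped into synteny blocks."""

    pillars: List[Pillar]
    genomes: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.genomes = tuple(self.genomes)
        for i, p in enumerate(self.pillars):
            if p.index != i:
                raise ValidationError(
                    f"pillar indices must be consecutive from 0; got {p.index} at {i}"
                )
            for g in p.slots:
                if g not in self.genomes:
                    raise ValidationError(f"pillar {i}: unknown genome {g}")
        seen = set()
        prev = None
        for p in self.pillars:
            if p.block_id != prev:
                if p.block_id in seen:
                    raise ValidationError(
                        f"block {p.block_id!r} is not contiguous in pillar order"
                    )
                seen.add(p.block_id)
                prev = p.block_id
        # duplicate gene ids within a genome across the whole set
        for g in self.genomes:
            ids: set = set()
            for p in self.pillars:
                for gid in p.genes(g):
                    if gid in ids:
                        raise ValidationError(f"duplicate gene id {gid} in genome {g}")
                    ids.add(gid)

    def __len__(self) -> int:
        return len(self.pillars)

    def __iter__(self):
        return iter(self.pillars)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def n_genes(self) -> int:
        return sum(p.n_genes for p in self.pillars)

    def presence_matrix(self) -> np.ndarray:
        """(n_pillars, n_genomes) matrix of presence classes."""
        mat = np.zeros((len(self.pillars), len(self.genomes)), dtype=np.int8)
        for i, p in enumerate(self.pillars):
            for j, g in enumerate(self.genomes):
                mat[i, j] = p.presence(g)
        return mat

    def block_bounds(self) -> List[Tuple[int, int]]:
        """Half-open [start, end) pillar-index ranges of each block, in order."""
        bounds: List[Tuple[int, int]] = []
        start = 0
        for i in range(1, len(self.pillars) + 1):
            if i == len(self.pillars) or self.pillars[i].block_id != self.pillars[start].block_id:
                bounds.append((start, i))
                start = i
        return bounds


@dataclass(frozen=True)
class OrthologyConfiguration:
    """Assignment of each genome's tracks to the two parental subgenomes.

    Encoded as a bitmask over the genome order: bit ``i`` clear means genome
    ``i`` is IDENTITY (track A -> subgenome 1, track B -> subgenome 2); bit
    set means SWAPPED.  For n genomes there are exactly 2^n configurations.
    """

    genomes: Tuple[str, ...]
    bits: int

    def __post_init__(self) -> None:
        if not 0 <= self.bits < (1 << len(self.genomes)):
            raise ValidationError("configuration bits out of range")

    def is_swapped(self, genome_index: int) -> bool:
        return bool((self.bits >> genome_index) & 1)

    @property
    def assignment(self) -> Dict[str, str]:
        return {
            g: (SWAPPED if self.is_swapped(i) else IDENTITY)
            for i, g in enumerate(self.genomes)
        }

    def bitstring(self) -> str:
        """Genome-ordered bitstring, first genome first; '0' = IDENTITY."""
        return "".join(str((self.bits >> i) & 1) for i in range(len(self.genomes)))

    def complement(self) -> "OrthologyConfiguration":
        """Global label swap: every genome's assignment flipped."""
        return OrthologyConfiguration(
            self.genomes, self.bits ^ ((1 << len(self.genomes)) - 1)
        )

    def track_of_subgenome(self, genome_index: int, subgenome: int) -> int:
        """Which track (0=A, 1=B) holds the given subgenome (1 or 2)."""
        if subgenome not in (1, 2):
            raise ValidationError("subgenome must be 1 or 2")
        base = 0 if subgenome == 1 else 1
        return base ^ int(self.is_swapped(genome_index))
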