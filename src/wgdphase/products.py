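"""Downstream deliverables: per-pillar gene trees, batch ortholog queries and
CDS bundles.

A pillar's gene tree is built by joining two mirrored copies of the species
tree at the WGD node — one copy per subgenome, subgenome 1 first — relabeling
each tip with the gene the decoded configuration assigns to that
genome x subgenome, pruning tips with no surviving gene, and suppressing the
resulting degree-2 nodes.  Branch lengths are the fitted loss-model lengths
(event scale, not substitutions).

Batch queries select pillars by orthology confidence and copy-number class,
optionally restricted to single-copy orthologs from the less or the more
fractionated subgenome, and bundle per-pillar FASTA + Newick files into a
POSIX tar archive with a manifest.
"""

from __future__ import annotations

import io as _io
import logging
import tarfile
from dataclasses import dataclass
from typing import Dict, List, Optional, Set

from .datamodel import OrthologyConfiguration, Pillar, PillarSet, SpeciesTree
from .errors import DegenerateTreeError, ValidationError
from .hmm import PosteriorTable
from .io import fasta_bytes
from .loss_model import LossModel

logger = logging.getLogger(__name__)

NONE = "NONE"
LESS_FRACTIONATED = "LESS_FRACTIONATED"
MORE_FRACTIONATED = "MORE_FRACTIONATED"


# ---------------------------------------------------------------------------
# Gene trees


class _Node:
    __slots__ = ("label", "length", "children")

    def __init__(self, label=None, length=0.0, children=None):
        self.label = label
        self.length = length
        self.children = children or []


def pillar_gene_tree(
    pillar: Pillar,
    config: OrthologyConfiguration,
    tree: SpeciesTree,
) -> str:
    """Newick gene tree for one pillar under its decoded configuration.

    Raises :class:`DegenerateTreeError` when fewer than two genes survive.
    """
    if pillar.n_genes < 2:
        raise DegenerateTreeError(
            f"pillar {pillar.index} has {pillar.n_genes} gene(s); no tree"
        )

    def copy_for_subgenome(sub: int) -> Optional[_Node]:
        def build(node: int) -> Optional[_Node]:
            length = float(tree.lengths[node])
            if tree.is_tip(node):
                genome = tree.tip_names[tree.tip_nodes.index(node)]
                gi = config.genomes.index(genome)
                track = config.track_of_subgenome(gi, sub)
                gid = pillar.slots.get(genome, (None, None))[track]
                if gid is None:
                    return None
                return _Node(label=gid, length=length)
            kids = [build(c) for c in tree.children[node]]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:  # suppress degree-2 node
                kids[0].length += length
                return kids[0]
            return _Node(length=length, children=kids)

        return build(tree.root)

    halves = [copy_for_subgenome(1), copy_for_subgenome(2)]
    halves = [h for h in halves if h is not None]
    if not halves:
        raise DegenerateTreeError(f"pillar {pillar.index}: no surviving genes")
    if len(halves) == 1:
        root = halves[0]
        root.length = 0.0  # the WGD node collapses onto the single mirror
    else:
        root = _Node(children=halves)
    return _newick(root) + ";"


def _newick(node: _Node) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.6g}"
    inner = ",".join(_newick(c) for c in node.children)
    if node.length > 0:
        return f"({inner}):{node.length:.6g}"
    return f"({inner})"


# ---------------------------------------------------------------------------
# Fractionation polarity


def less_fractionated_subgenome(
    pillars: PillarSet,
    posterior: PosteriorTable,
    model: LossModel,
) -> int:
    """Which subgenome (1 or 2) has retained more genes.

    By the model's construction subgenome 1 is the favoured one whenever the
    fitted epsilon < 1; at epsilon = 1 the labels are symmetric and empirical
    single-copy survivor counts decide, with ties to subgenome 1.
    """
    if model.epsilon < 1.0:
        return 1
    counts = {1: 0, 2: 0}
    for i, pillar in enumerate(pillars):
        config = posterior.viterbi_config(i)
        for gi, g in enumerate(config.genomes):
            a, b = pillar.slots.get(g, (None, None))
            if (a is None) == (b is None):
                continue  # both or neither: no fractionation signal
            on_a = a is not None
            sub = 1 if on_a != config.is_swapped(gi) else 2
            counts[sub] += 1
    return 1 if counts[1] >= counts[2] else 2


# ---------------------------------------------------------------------------
# Batch queries


@dataclass
class QuerySpec:
    """Pillar selection criteria for a batch download."""

    min_confidence: float = 0.0
    copy_classes: Optional[Set[int]] = None  # allowed duplicated-genome counts
    single_copy_orthologs: bool = False
    subgenome_restrict: str = NONE

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValidationError("min_confidence must be in [0, 1]")
        if self.subgenome_restrict not in (NONE, LESS_FRACTIONATED, MORE_FRACTIONATED):
            raise ValidationError(f"bad subgenome restriction {self.subgenome_restrict}")
        if self.single_copy_orthologs:
            # single-copy orthologs means zero duplicated genomes by definition
            self.copy_classes = {0}


@dataclass
class QueryResult:
    selected: List[int]
    manifest: List[Dict[str, object]]
    skipped_genes: List[str]


def select_pillars(
    pillars: PillarSet,
    posterior: PosteriorTable,
    query: QuerySpec,
    model: Optional[LossModel] = None,
) -> List[int]:
    """Indices of pillars meeting the query criteria."""
    restrict_sub = None
    if query.subgenome_restrict != NONE:
        if model is None:
            raise ValidationError("subgenome restriction needs the fitted model")
        less = less_fractionated_subgenome(pillars, posterior, model)
        restrict_sub = (
            less if query.subgenome_restrict == LESS_FRACTIONATED else 3 - less
        )
    conf = posterior.confidence
    out: List[int] = []
    for i, pillar in enumerate(pillars):
        if pillar.n_genes < 2:
            continue
        if conf[i] < query.min_confidence:
            continue
        config = posterior.viterbi_config(i)
        n_dup = 0
        subs: Set[int] = set()
        all_single = True
        for gi, g in enumerate(config.genomes):
            a, b = pillar.slots.get(g, (None, None))
            present = (a is not None) + (b is not None)
            if present == 0:
                continue
            if present == 2:
                n_dup += 1
                all_single = False
            else:
                on_a = a is not None
                subs.add(1 if on_a != config.is_swapped(gi) else 2)
        if query.copy_classes is not None and n_dup not in query.copy_classes:
            continue
        if query.single_copy_orthologs:
            if not all_single or len(subs) != 1:
                continue
            if restrict_sub is not None and subs != {restrict_sub}:
                continue
        out.append(i)
    return out


def batch_query(
    pillars: PillarSet,
    posterior: PosteriorTable,
    tree: SpeciesTree,
    query: QuerySpec,
    cds: Dict[str, str],
    out_path: str,
    model: Optional[LossModel] = None,
) -> QueryResult:
    """Write a tar archive of per-pillar FASTA + Newick for matching pillars.

    An empty selection still yields a valid archive containing only the
    manifest.  Genes missing from the CDS store are skipped with a warning
    and noted in the manifest.
    """
    selected = select_pillars(pillars, posterior, query, model=model)
    manifest: List[Dict[str, object]] = []  # one row per emitted file
    skipped: List[str] = []
    with tarfile.open(out_path, "w") as tar:
        for i in selected:
            pillar = pillars.pillars[i]
            config = posterior.viterbi_config(i)
            genes = pillar.genes()
            seqs = {}
            missing_cds = []
            for gid in genes:
                if gid in cds:
                    seqs[gid] = cds[gid]
                else:
                    logger.warning("no CDS for gene %s; skipped", gid)
                    missing_cds.append(gid)
                    skipped.append(gid)
            meta = {
                "pillar": i,
                "block": pillar.block_id,
                "confidence": float(posterior.confidence[i]),
                "config": config.bitstring(),
                "n_genes": len(genes),
                "missing_cds": ",".join(missing_cds) or "-",
            }
            if seqs:
                name = f"pillar_{i}.fa"
                _add_member(tar, name, fasta_bytes(seqs))
                manifest.append({"file": name, **meta})
            try:
                nwk = pillar_gene_tree(pillar, config, tree)
            except DegenerateTreeError:
                nwk = None
            if nwk is not None:
                name = f"pillar_{i}.nwk"
                _add_member(tar, name, (nwk + "\n").encode())
                manifest.append({"file": name, **meta})
        _add_member(tar, "MANIFEST.tsv", _manifest_bytes(manifest))
    return QueryResult(selected=selected, manifest=manifest, skipped_genes=skipped)


def _manifest_bytes(manifest: List[Dict[str, object]]) -> bytes:
    lines = ["#file\tpillar\tblock\tconfidence\tconfig\tn_genes\tmissing_cds"]
    for row in manifest:
        lines.append(
            "\t".join(
                [
                    str(row["file"]),
                    str(row["pillar"]),
                    str(row["block"]),
                    f"{row['confidence']:.6f}",
                    str(row["config"]),
                    str(row["n_genes"]),
                    str(row["missing_cds"]),
                ]
            )
        )
    return ("\n".join(lines) + "\n").encode()


def _add_member(tar: tarfile.TarFile, name: str, data: bytes) -> None:
    info = tarfile.TarInfo(name=name)
    info.size = len(data)
    info.mtime = 0  # deterministic archives
    tar.addfile(info, _io.BytesIO(data))
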