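"""Readers and writers for every on-disk format the tool touches.

Formats:

* Species tree — Newick with branch lengths.  An optional length on the
  outermost clade is read as the stem branch between the WGD event and the
  first divergence.
* Pillar table — tab-delimited; header ``#pillar<TAB>block<TAB><genome>_A
  <TAB><genome>_B ...`` then one row per pillar: integer index, block id, and
  two fields per genome (gene id or the absence token ``-``).
* Gene order — per-genome tab-delimited file: chromosome, start, end,
  gene id, strand (1-based inclusive coordinates).
* CDS — FASTA keyed by gene id (Biopython under the hood).
* Config — flat ``key = value`` text.
"""

from __future__ import annotations

import io as _io
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import Gene, Pillar, PillarSet, SpeciesTree
from .errors import FormatError, ValidationError

ABSENT = "-"


# ---------------------------------------------------------------------------
# Species tree


def read_species_tree(path: str, default_stem: float = 0.1) -> SpeciesTree:
    """Parse a rooted bifurcating Newick tree with branch lengths.

    A length on the outermost clade (``(...):x;``) becomes the stem branch;
    otherwise ``default_stem`` is used.  Multifurcations (including the
    trifurcating root of an unrooted tree) are format errors; negative branch
    lengths are validation errors.
    """
    with open(path) as fh:
        text = fh.read()
    return parse_species_tree(text, default_stem=default_stem)


def parse_species_tree(newick: str, default_stem: float = 0.1) -> SpeciesTree:
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick: {exc}") from exc

    seed = dtree.seed_node
    stem = seed.edge.length if seed.edge.length is not None else default_stem
    # An outermost one-child clade encodes the stem: "((A,B):0.2);" is a
    # 2-tip tree whose stem branch is 0.2.
    kids = seed.child_nodes()
    if len(kids) == 1:
        inner = kids[0]
        if inner.edge.length is not None:
            stem = inner.edge.length
        if inner.is_leaf():
            # single-genome tree: the only branch is the stem itself
            if stem < 0:
                raise ValidationError("negative branch length")
            name = inner.taxon.label if inner.taxon else "tip"
            return SpeciesTree(
                parent=[None], children=[()], lengths=[float(stem)],
                tip_names=[name], tip_nodes=[0],
            )
        seed = inner

    parent: List[Optional[int]] = []
    children: List[Tuple[int, ...]] = []
    lengths: List[float] = []
    tip_names: List[str] = []
    tip_nodes: List[int] = []

    def build(node, parent_index: Optional[int]) -> int:
        idx = len(parent)
        parent.append(parent_index)
        children.append(())
        if node is seed:
            length = stem
        else:
            length = node.edge.length
            if length is None:
                raise FormatError("branch length missing in Newick")
        if length < 0:
            raise ValidationError("negative branch length")
        lengths.append(float(length))
        node_kids = node.child_nodes()
        if node.is_leaf():
            name = node.taxon.label if node.taxon else None
            if not name:
                raise FormatError("unnamed tip in Newick")
            tip_names.append(name)
            tip_nodes.append(idx)
        elif len(node_kids) == 2:
            children[idx] = tuple(build(k, idx) for k in node_kids)
        else:
            raise FormatError(
                f"node with {len(node_kids)} children: tree must be rooted "
                "and bifurcating"
            )
        return idx

    build(seed, None)
    return SpeciesTree(parent, children, lengths, tip_names, tip_nodes)


def write_species_tree(tree: SpeciesTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# Pillar table


def read_pillars(path: str, genomes: Sequence[str]) -> PillarSet:
    """Read the tab-delimited pillar table for the given ordered genomes."""
    genomes = tuple(genomes)
    expected_cols = 2 + 2 * len(genomes)
    pillars: List[Pillar] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                _check_header(line, genomes, lineno)
                continue
            fields = line.split("\t")
            if len(fields) != expected_cols:
                raise FormatError(
                    f"line {lineno}: expected {expected_cols} columns, "
                    f"got {len(fields)}"
                )
            try:
                index = int(fields[0])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad pillar index {fields[0]!r}") from exc
            block_id = fields[1]
            slots: Dict[str, Tuple[Optional[str], Optional[str]]] = {}
            for j, g in enumerate(genomes):
                a, b = fields[2 + 2 * j], fields[3 + 2 * j]
                slots[g] = (_slot(a, lineno), _slot(b, lineno))
            try:
                pillars.append(Pillar(index=index, block_id=block_id, slots=slots))
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
    return PillarSet(pillars=pillars, genomes=genomes)


def _slot(token: str, lineno: int) -> Optional[str]:
    if token == ABSENT:
        return None
    if token == "":
        raise FormatError(f"line {lineno}: empty field (use '{ABSENT}' for absence)")
    return token


def _check_header(line: str, genomes: Sequence[str], lineno: int) -> None:
    fields = line.lstrip("#").split("\t")
    expected = ["pillar", "block"]
    for g in genomes:
        expected += [f"{g}_A", f"{g}_B"]
    if fields != expected:
        raise FormatError(
            f"line {lineno}: header does not match genomes {list(genomes)}"
        )


def write_pillars(pillar_set: PillarSet, path: str) -> None:
    with open(path, "w") as fh:
        header = ["pillar", "block"]
        for g in pillar_set.genomes:
            header += [f"{g}_A", f"{g}_B"]
        fh.write("#" + "\t".join(header) + "\n")
        for p in pillar_set.pillars:
            row = [str(p.index), p.block_id]
            for g in pillar_set.genomes:
                a, b = p.slots.get(g, (None, None))
                row += [a or ABSENT, b or ABSENT]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Gene order (BED-like, but 1-based inclusive)


def read_gene_order(path: str, genome: str) -> Dict[str, Gene]:
    """Read one genome's gene coordinates; returns gene_id -> Gene."""
    genes: Dict[str, Gene] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(
                    f"line {lineno}: expected >=5 columns "
                    "(chrom, start, end, gene_id, strand)"
                )
            chrom, start, end, gene_id, strand = fields[:5]
            common = fields[5] if len(fields) > 5 and fields[5] else None
            try:
                gene = Gene(
                    gene_id=gene_id, genome=genome, chromosome=chrom,
                    start=int(start), end=int(end), strand=strand,
                    common_name=common,
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad coordinates") from exc
            if gene_id in genes:
                raise ValidationError(
                    f"line {lineno}: duplicate gene id {gene_id} in {genome}"
                )
            genes[gene_id] = gene
    return genes


def write_gene_order(genes: Sequence[Gene], path: str) -> None:
    ordered = sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
    with open(path, "w") as fh:
        for g in ordered:
            row = [g.chromosome, str(g.start), str(g.end), g.gene_id, g.strand]
            if g.common_name:
                row.append(g.common_name)
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> Dict[str, str]:
    """Read FASTA into an id -> sequence dict; duplicate ids are errors."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA id {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Dict[str, str], path_or_handle) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    if isinstance(path_or_handle, str):
        with open(path_or_handle, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, path_or_handle, "fasta")


def fasta_bytes(seqs: Dict[str, str]) -> bytes:
    buf = _io.StringIO()
    write_fasta(seqs, buf)
    return buf.getvalue().encode()


# ---------------------------------------------------------------------------
# Flat key = value config


def read_config(path: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def write_config(values: Dict[str, object], path: str) -> None:
    with open(path, "w") as fh:
        for key, value in values.items():
            fh.write(f"{key} = {value}\n")
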