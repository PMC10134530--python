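import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from wgdphase.datamodel import Pillar, PillarSet
from wgdphase.io import parse_species_tree


@pytest.fixture
def tree1():
    """Single-genome tree; the only branch is the stem."""
    return parse_species_tree("(A:0.4);")


@pytest.fixture
def tree2():
    """Two genomes, stem 0.2."""
    return parse_species_tree("((A:0.3,B:0.3):0.2);")


@pytest.fixture
def tree3():
    return parse_species_tree("((A:0.1,B:0.1):0.2,C:0.3):0.15;")


@pytest.fixture
def tree4():
    """Four genomes in the moderate simulation regime (all branches 0.3)."""
    return parse_species_tree("(((A:0.3,B:0.3):0.3,C:0.3):0.3,D:0.3):0.3;")


def make_pillars(rows, genomes, blocks=None):
    """Build a PillarSet from per-pillar {genome: (a, b)} dicts."""
    pillars = []
    for i, slots in enumerate(rows):
        block = blocks[i] if blocks else "blk1"
        pillars.append(Pillar(index=i, block_id=block, slots=dict(slots)))
    return PillarSet(pillars=pillars, genomes=tuple(genomes))


@pytest.fixture
def pillars_ab():
    """Five 2-genome pillars mixing duplicated, single-copy and missing."""
    return make_pillars(
        [
            {"A": ("a0x", "a0y"), "B": ("b0x", "b0y")},
            {"A": ("a1x", None), "B": ("b1x", None)},
            {"A": (None, "a2y"), "B": ("b2x", None)},
            {"A": ("a3x", "a3y"), "B": (None, None)},
            {"A": ("a4x", None), "B": (None, "b4y")},
        ],
        ["A", "B"],
    )


def random_patterns(rng, n_pillars, n_genomes):
    """Presence classes with at least one gene somewhere per pillar."""
    pats = rng.integers(0, 4, size=(n_pillars, n_genomes))
    empty = (pats == 0).all(axis=1)
    pats[empty, 0] = rng.integers(1, 4, size=int(empty.sum()))
    return pats


def pillars_from_patterns(pats, genomes, blocks=None):
    rows = []
    for i, row in enumerate(pats):
        slots = {}
        for j, g in enumerate(genomes):
            a = f"{g}{i}a" if row[j] in (1, 3) else None
            b = f"{g}{i}b" if row[j] in (2, 3) else None
            slots[g] = (a, b)
        rows.append(slots)
    return make_pillars(rows, genomes, blocks=blocks)
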