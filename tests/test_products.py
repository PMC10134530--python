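"""Gene trees, batch queries and archive contracts."""

import tarfile

import dendropy
import numpy as np
import pytest

from wgdphase.datamodel import OrthologyConfiguration, Pillar
from wgdphase.errors import DegenerateTreeError
from wgdphase.hmm import RECIPROCAL_LOSS, classify_pillar, decode
from wgdphase.loss_model import LossModel
from wgdphase.products import (
    LESS_FRACTIONATED,
    QuerySpec,
    batch_query,
    less_fractionated_subgenome,
    pillar_gene_tree,
    select_pillars,
)
from wgdphase.simulate import SimulationConfig, simulate


def _parse(nwk):
    return dendropy.Tree.get(data=nwk, schema="newick")


def _leaves(nwk):
    return {t.label for t in _parse(nwk).taxon_namespace}


class TestGeneTree:
    def test_fully_duplicated_gives_two_mirrored_copies(self, tree3):
        pillar = Pillar(
            0, "b",
            {"A": ("a1", "a2"), "B": ("b1", "b2"), "C": ("c1", "c2")},
        )
        config = OrthologyConfiguration(("A", "B", "C"), 0)
        nwk = pillar_gene_tree(pillar, config, tree3)
        tree = _parse(nwk)
        assert len(tree.leaf_nodes()) == 6
        halves = tree.seed_node.child_nodes()
        assert len(halves) == 2
        sides = [
            {leaf.taxon.label for leaf in half.leaf_iter()} for half in halves
        ]
        # subgenome 1 mirror first (track A under the identity configuration)
        assert sides[0] == {"a1", "b1", "c1"}
        assert sides[1] == {"a2", "b2", "c2"}

    def test_all_single_copy_matches_species_tree_shape(self, tree3):
        pillar = Pillar(
            0, "b", {"A": ("a1", None), "B": ("b1", None), "C": ("c1", None)}
        )
        config = OrthologyConfiguration(("A", "B", "C"), 0)
        nwk = pillar_gene_tree(pillar, config, tree3)
        tree = _parse(nwk)
        assert len(tree.leaf_nodes()) == 3
        # topology ((a1,b1),c1) mirrors the species tree ((A,B),C)
        ab = {
            frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            for node in tree.seed_node.child_nodes()
        }
        assert frozenset({"a1", "b1"}) in ab

    def test_reciprocal_loss_pair_joined_at_wgd_node(self, tree2):
        pillar = Pillar(0, "b", {"A": ("a1", None), "B": (None, "b1")})
        config = OrthologyConfiguration(("A", "B"), 0)
        nwk = pillar_gene_tree(pillar, config, tree2)
        tree = _parse(nwk)
        assert _leaves(nwk) == {"a1", "b1"}
        # the two paralogs attach directly to the root (the WGD event)
        assert all(k.is_leaf() for k in tree.seed_node.child_nodes())

    def test_swapped_configuration_routes_genes(self, tree2):
        pillar = Pillar(0, "b", {"A": ("a1", "a2"), "B": ("b1", "b2")})
        config = OrthologyConfiguration(("A", "B"), 0b10)  # B swapped
        nwk = pillar_gene_tree(pillar, config, tree2)
        halves = _parse(nwk).seed_node.child_nodes()
        side1 = {leaf.taxon.label for leaf in halves[0].leaf_iter()}
        assert side1 == {"a1", "b2"}

    def test_degenerate_pillar_refused(self, tree2):
        pillar = Pillar(0, "b", {"A": ("a1", None), "B": (None, None)})
        config = OrthologyConfiguration(("A", "B"), 0)
        with pytest.raises(DegenerateTreeError):
            pillar_gene_tree(pillar, config, tree2)


@pytest.fixture(scope="module")
def inferred4():
    from wgdphase.io import parse_species_tree

    tree = parse_species_tree("(((A:0.3,B:0.3):0.3,C:0.3):0.3,D:0.3):0.3;")
    sim = simulate(
        SimulationConfig(tree=tree, n_pillars=400, n_blocks=2,
                         phi=0.5, epsilon=0.5, s=0.02, seed=21)
    )
    model = LossModel(0.5, 0.5)
    post = decode(sim.pillars, tree, model, 0.02)
    return sim, tree, model, post


class TestBatchQuery:
    def test_every_emitted_tree_reparses_with_right_tip_count(self, inferred4, tmp_path):
        sim, tree, model, post = inferred4
        out = tmp_path / "all.tar"
        result = batch_query(
            sim.pillars, post, tree, QuerySpec(), sim.cds, str(out), model=model
        )
        with tarfile.open(out) as tar:
            names = tar.getnames()
            for row in result.manifest:
                if not row["file"].endswith(".nwk"):
                    continue
                nwk = tar.extractfile(row["file"]).read().decode()
                assert len(_parse(nwk).leaf_nodes()) == row["n_genes"]
        assert "MANIFEST.tsv" in names

    def test_min_confidence_zero_selects_every_multi_gene_pillar(self, inferred4):
        sim, tree, model, post = inferred4
        selected = select_pillars(sim.pillars, post, QuerySpec(min_confidence=0.0))
        expected = [i for i, p in enumerate(sim.pillars) if p.n_genes >= 2]
        assert selected == expected

    def test_monotone_in_confidence_threshold(self, inferred4):
        sim, tree, model, post = inferred4
        counts = [
            len(select_pillars(sim.pillars, post, QuerySpec(min_confidence=c)))
            for c in np.linspace(0, 1, 11)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_single_copy_orthologs_all_on_one_subgenome(self, inferred4):
        sim, tree, model, post = inferred4
        query = QuerySpec(min_confidence=0.95, single_copy_orthologs=True)
        for i in select_pillars(sim.pillars, post, query, model=model):
            pillar = sim.pillars.pillars[i]
            config = post.viterbi_config(i)
            subs = set()
            for gi, g in enumerate(config.genomes):
                a, b = pillar.slots[g]
                assert (a is None) != (b is None)  # exactly one gene
                on_a = a is not None
                subs.add(1 if on_a != config.is_swapped(gi) else 2)
            assert len(subs) == 1

    def test_single_copy_query_excludes_true_reciprocal_losses(self):
        """Confident single-copy ortholog pillars must not be pillars where
        the truth says alternative copies were lost (paralogs).

        Uses switch-free tracking, where subgenome assignment is fully
        identifiable; with switches the exact switch pillar is not.
        """
        from wgdphase.io import parse_species_tree

        tree = parse_species_tree("(((A:0.3,B:0.3):0.3,C:0.3):0.3,D:0.3):0.3;")
        model = LossModel(0.5, 0.5)
        sim = simulate(
            SimulationConfig(tree=tree, n_pillars=400, n_blocks=2,
                             phi=0.5, epsilon=0.5, s=0.0, seed=21)
        )
        post = decode(sim.pillars, tree, model, 0.0)
        query = QuerySpec(min_confidence=0.95, single_copy_orthologs=True)
        selected = select_pillars(sim.pillars, post, query, model=model)
        assert selected  # the regime yields confident single-copy pillars
        truth_bits = sim.truth.true_config_bits()
        for i in selected:
            pillar = sim.pillars.pillars[i]
            true_cfg = OrthologyConfiguration(sim.truth.genomes, int(truth_bits[i]))
            assert classify_pillar(pillar, true_cfg) != RECIPROCAL_LOSS

    def test_manifest_rows_equal_archive_files(self, inferred4, tmp_path):
        sim, tree, model, post = inferred4
        out = tmp_path / "q.tar"
        result = batch_query(
            sim.pillars, post, tree,
            QuerySpec(min_confidence=0.5), sim.cds, str(out), model=model,
        )
        with tarfile.open(out) as tar:
            data_files = [n for n in tar.getnames() if n != "MANIFEST.tsv"]
            manifest_text = tar.extractfile("MANIFEST.tsv").read().decode()
        assert len(result.manifest) == len(data_files)
        assert len(manifest_text.strip().splitlines()) - 1 == len(data_files)

    def test_empty_selection_still_writes_manifest(self, inferred4, tmp_path):
        sim, tree, model, post = inferred4
        out = tmp_path / "empty.tar"
        result = batch_query(
            sim.pillars, post, tree,
            QuerySpec(min_confidence=1.0, copy_classes={99}),
            sim.cds, str(out), model=model,
        )
        assert result.selected == []
        with tarfile.open(out) as tar:
            assert tar.getnames() == ["MANIFEST.tsv"]

    def test_missing_cds_skipped_and_recorded(self, inferred4, tmp_path):
        sim, tree, model, post = inferred4
        cds = dict(sim.cds)
        victim = sim.pillars.pillars[0].genes()[0]
        del cds[victim]
        out = tmp_path / "m.tar"
        result = batch_query(
            sim.pillars, post, tree, QuerySpec(), cds, str(out), model=model
        )
        assert victim in result.skipped_genes

    def test_less_fractionated_is_subgenome_one_under_bias(self, inferred4):
        sim, tree, model, post = inferred4
        assert less_fractionated_subgenome(sim.pillars, post, model) == 1
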