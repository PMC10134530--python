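"""The configuration-tracking HMM: enumeration, emissions, decoding."""

import numpy as np
import pytest

from wgdphase.datamodel import OrthologyConfiguration, Pillar
from wgdphase.errors import CapabilityError
from wgdphase.hmm import (
    DUPLICATED,
    MIXED,
    RECIPROCAL_LOSS,
    SINGLE_SUB1,
    SINGLE_SUB2,
    HMMSpec,
    classify_pillar,
    decode,
    emission_matrix,
    enumerate_configurations,
    forward_backward,
    viterbi,
)
from wgdphase.loss_model import LossModel

from conftest import make_pillars, pillars_from_patterns, random_patterns
from oracles import exhaustive_posteriors, exhaustive_viterbi, _path_log_prob


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(1, 2), (2, 4), (6, 64)])
    def test_counts(self, n, expected):
        genomes = tuple(f"G{i}" for i in range(n))
        configs = enumerate_configurations(genomes)
        assert len(configs) == expected
        assert len({c.bits for c in configs}) == expected
        # deterministic binary order, IDENTITY = 0 bit
        assert configs[0].bits == 0
        assert [c.bits for c in configs] == list(range(expected))

    def test_out_of_range(self):
        with pytest.raises(CapabilityError):
            enumerate_configurations(())
        with pytest.raises(CapabilityError):
            enumerate_configurations(tuple(f"G{i}" for i in range(13)))

    def test_warns_above_eight(self):
        with pytest.warns(UserWarning):
            enumerate_configurations(tuple(f"G{i}" for i in range(9)))


class TestEmissions:
    def test_fully_duplicated_pillar_config_invariant(self, tree2):
        ps = make_pillars(
            [{"A": ("a1", "a2"), "B": ("b1", "b2")}], ["A", "B"]
        )
        log_e = emission_matrix(ps, tree2, LossModel(0.5, 0.3))
        assert np.ptp(log_e[0]) <= 1e-12

    def test_single_genome_entries_differ_unless_unbiased(self, tree1):
        ps = make_pillars([{"A": ("a1", None)}], ["A"])
        biased = emission_matrix(ps, tree1, LossModel(0.5, 0.4))[0]
        assert abs(biased[0] - biased[1]) > 1e-6
        unbiased = emission_matrix(ps, tree1, LossModel(0.5, 1.0))[0]
        assert abs(unbiased[0] - unbiased[1]) <= 1e-12

    def test_likelihoods_bounded(self, tree2, pillars_ab):
        log_e = emission_matrix(pillars_ab, tree2, LossModel(0.5, 0.3))
        assert (log_e <= 0.0).all()
        assert np.exp(log_e).sum(axis=1).max() <= 4.0


def _hmm(ps, s):
    return HMMSpec(genomes=ps.genomes, switch_prob=s, block_bounds=ps.block_bounds())


class TestForwardBackward:
    def test_single_pillar_posterior_is_normalized_emission(self, tree2):
        ps = make_pillars([{"A": ("a1", None), "B": (None, "b1")}], ["A", "B"])
        log_e = emission_matrix(ps, tree2, LossModel(0.5, 0.3))
        post, _ = forward_backward(log_e, _hmm(ps, 0.1))
        expected = np.exp(log_e[0]) / np.exp(log_e[0]).sum()
        assert np.abs(post[0] - expected).max() <= 1e-12

    def test_frozen_chain_shares_posterior_across_block(self, tree2):
        rng = np.random.default_rng(0)
        ps = pillars_from_patterns(random_patterns(rng, 3, 2), ["A", "B"])
        log_e = emission_matrix(ps, tree2, LossModel(0.5, 0.3))
        post, _ = forward_backward(log_e, _hmm(ps, 0.0))
        assert np.abs(post - post[0]).max() <= 1e-9
        expected = np.exp(log_e.sum(axis=0) - log_e.sum(axis=0).max())
        expected /= expected.sum()
        assert np.abs(post[0] - expected).max() <= 1e-9

    def test_posteriors_normalized(self, tree2, pillars_ab):
        log_e = emission_matrix(pillars_ab, tree2, LossModel(0.5, 0.3))
        post, _ = forward_backward(log_e, _hmm(pillars_ab, 0.05))
        assert np.abs(post.sum(axis=1) - 1.0).max() <= 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_path_sum(self, tree2, seed):
        rng = np.random.default_rng(seed)
        n_pillars = 4
        blocks = ["b1", "b1", "b2", "b2"]
        ps = pillars_from_patterns(
            random_patterns(rng, n_pillars, 2), ["A", "B"], blocks=blocks
        )
        log_e = rng.normal(-2.0, 1.0, size=(n_pillars, 4))
        post, log_lik = forward_backward(log_e, _hmm(ps, 0.1))
        block_of = [0, 0, 1, 1]
        exp_post, exp_ll = exhaustive_posteriors(log_e, 0.1, 2, block_of)
        assert log_lik == pytest.approx(exp_ll, abs=1e-8)
        assert np.abs(post - exp_post).max() <= 1e-8

    def test_unbiased_data_posterior_symmetric(self, tree2):
        """eps=1: a config and its global complement are equally probable,
        so Viterbi confidence cannot exceed one half."""
        rng = np.random.default_rng(1)
        ps = pillars_from_patterns(random_patterns(rng, 8, 2), ["A", "B"])
        table = decode(ps, tree2, LossModel(0.5, 1.0), 0.05)
        post = table.posteriors
        comp = post[:, [3, 2, 1, 0]]  # bits ^ 0b11
        assert np.abs(post - comp).max() <= 1e-9
        assert table.confidence.max() <= 0.5 + 1e-9

    def test_biased_data_breaks_symmetry(self, tree2):
        ps = make_pillars(
            [{"A": (f"a{i}", None), "B": (f"b{i}", None)} for i in range(3)],
            ["A", "B"],
        )
        table = decode(ps, tree2, LossModel(0.5, 0.2), 0.05)
        assert table.confidence.max() > 0.5


class TestViterbi:
    def test_single_pillar_argmax(self, tree2, pillars_ab):
        log_e = emission_matrix(pillars_ab, tree2, LossModel(0.5, 0.3))[:1]
        hmm = HMMSpec(
            genomes=pillars_ab.genomes, switch_prob=0.1, block_bounds=[(0, 1)]
        )
        path = viterbi(log_e, hmm)
        assert path[0] == np.argmax(log_e[0])

    def test_frozen_chain_constant_path(self, tree2):
        rng = np.random.default_rng(2)
        ps = pillars_from_patterns(random_patterns(rng, 5, 2), ["A", "B"])
        log_e = emission_matrix(ps, tree2, LossModel(0.5, 0.3))
        path = viterbi(log_e, _hmm(ps, 0.0))
        assert len(set(path.tolist())) == 1
        assert path[0] == np.argmax(log_e.sum(axis=0))

    @pytest.mark.parametrize("seed", range(5))
    def test_path_score_matches_exhaustive_max(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_pillars = 5
        log_e = rng.normal(-2.0, 1.0, size=(n_pillars, 4))
        hmm = HMMSpec(
            genomes=("A", "B"), switch_prob=0.1,
            block_bounds=[(0, 2), (2, 5)],
        )
        path = viterbi(log_e, hmm)
        block_of = [0, 0, 1, 1, 1]
        _, best_score = exhaustive_viterbi(log_e, 0.1, 2, block_of)
        got_score = _path_log_prob(tuple(path), log_e, 0.1, 2, block_of)
        assert got_score == pytest.approx(best_score, abs=1e-8)


class TestClassify:
    def _cfg(self, bits=0):
        return OrthologyConfiguration(("A", "B"), bits)

    def test_all_duplicated(self):
        p = Pillar(0, "b", {"A": ("a1", "a2"), "B": ("b1", "b2")})
        assert classify_pillar(p, self._cfg()) == DUPLICATED

    def test_reciprocal_loss(self):
        p = Pillar(0, "b", {"A": ("a1", None), "B": (None, "b1")})
        assert classify_pillar(p, self._cfg()) == RECIPROCAL_LOSS

    def test_mixed(self):
        p = Pillar(0, "b", {"A": ("a1", "a2"), "B": ("b1", None)})
        assert classify_pillar(p, self._cfg()) == MIXED

    def test_single_copy_subgenomes_follow_configuration(self):
        p = Pillar(0, "b", {"A": ("a1", None), "B": ("b1", None)})
        assert classify_pillar(p, self._cfg(0b00)) == SINGLE_SUB1
        assert classify_pillar(p, self._cfg(0b11)) == SINGLE_SUB2
        assert classify_pillar(p, self._cfg(0b01)) == RECIPROCAL_LOSS

    def test_missing_genomes_ignored(self):
        p = Pillar(0, "b", {"A": ("a1", None), "B": (None, None)})
        assert classify_pillar(p, self._cfg()) == SINGLE_SUB1
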