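import math

import numpy as np
import pytest

from conftest import random_sequence
from oracles import alignment_posteriors_by_enumeration, best_path_weight
from turbofold.alignment_hmm import (
    AlignmentModelParams,
    coincidence,
    constraint_sets,
    forward_backward,
    sequence_identity,
    viterbi,
    viterbi_score,
)
from turbofold.io_formats import RnaSequence


class TestParams:
    def test_stationarity_of_start_distribution(self, hmm_params):
        pi = hmm_params.start
        assert np.allclose(pi @ hmm_params.transition, pi)
        assert math.isclose(pi.sum(), 1.0)

    def test_invalid_blocks_rejected(self, hmm_params):
        bad_t = hmm_params.transition.copy()
        bad_t[0, 0] += 0.1
        with pytest.raises(ValueError):
            AlignmentModelParams(bad_t, hmm_params.match_emission, hmm_params.insert_emission)
        with pytest.raises(ValueError):
            AlignmentModelParams(
                hmm_params.transition,
                np.full((4, 4), 1 / 16.0) - np.eye(4) * 0.01,
                hmm_params.insert_emission,
            )


class TestForwardBackward:
    def test_single_residue_cell_mass_is_one(self, hmm_params):
        # every complete path visits lattice cell (1, 1)
        post, _ = forward_backward(RnaSequence("a", "A"), RnaSequence("b", "A"), hmm_params)
        assert math.isclose(post[:, 1, 1].sum(), 1.0, abs_tol=1e-12)

    def test_aln_posterior_rows_bounded_by_one(self, hmm_params):
        rng = np.random.default_rng(11)
        x = random_sequence(rng, 9, "x")
        y = random_sequence(rng, 7, "y")
        post, _ = forward_backward(x, y, hmm_params)
        # position i aligns to at most one k on any path
        assert np.all(post[0].sum(axis=1) <= 1 + 1e-12)
        assert np.all(post[0].sum(axis=0) <= 1 + 1e-12)

    def test_matches_exhaustive_enumeration(self, hmm_params):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n1, n2 = rng.integers(1, 6), rng.integers(1, 6)
            x = random_sequence(rng, n1, "x")
            y = random_sequence(rng, n2, "y")
            ref, z = alignment_posteriors_by_enumeration(x.residues, y.residues, hmm_params)
            post, log_z = forward_backward(x, y, hmm_params)
            assert np.max(np.abs(post - ref)) < 1e-10
            assert math.isclose(log_z, math.log(z), abs_tol=1e-10)

    def test_empty_sequence_rejected(self, hmm_params):
        with pytest.raises((ValueError, Exception)):
            forward_backward(RnaSequence("a", "A"), RnaSequence("b", ""), hmm_params)


class TestCoincidence:
    def test_single_vs_single_is_certain(self, hmm_params):
        cm = coincidence(RnaSequence("a", "G"), RnaSequence("b", "C"), hmm_params)
        assert math.isclose(cm.probs[0, 0], 1.0, abs_tol=1e-12)

    def test_exact_transpose_symmetry(self, hmm_params):
        rng = np.random.default_rng(13)
        x = random_sequence(rng, 12, "x")
        y = random_sequence(rng, 10, "y")
        cm_xy = coincidence(x, y, hmm_params)
        cm_yx = coincidence(y, x, hmm_params)
        assert np.array_equal(cm_xy.probs, cm_yx.probs.T)
        assert cm_xy.identity == cm_yx.identity

    def test_long_sequences_stay_finite(self, hmm_params):
        rng = np.random.default_rng(14)
        x = random_sequence(rng, 500, "x")
        y = random_sequence(rng, 500, "y")
        cm = coincidence(x, y, hmm_params)
        assert np.all(np.isfinite(cm.probs))
        assert 0.0 < cm.probs.max() <= 1.0


class TestViterbi:
    def test_identical_sequences_align_on_diagonal(self, hmm_params):
        x = RnaSequence("x", "ACGUACGU")
        y = RnaSequence("y", "ACGUACGU")
        path = viterbi(x, y, hmm_params)
        assert all(name == "ALN" for name, _, _ in path)
        assert [(i, k) for _, i, k in path] == [(t, t) for t in range(1, 9)]

    def test_score_matches_enumeration(self, hmm_params):
        rng = np.random.default_rng(15)
        for _ in range(20):
            x = random_sequence(rng, int(rng.integers(2, 6)), "x")
            y = random_sequence(rng, int(rng.integers(2, 6)), "y")
            assert math.isclose(
                viterbi_score(x, y, hmm_params),
                math.log(best_path_weight(x.residues, y.residues, hmm_params)),
                abs_tol=1e-10,
            )


class TestIdentity:
    def test_identical_and_disjoint_sequences(self, hmm_params):
        same = RnaSequence("a", "GCGCGC")
        assert sequence_identity(viterbi(same, same, hmm_params), same, same) == 1.0
        a, b = RnaSequence("a", "AAAA"), RnaSequence("b", "CCCC")
        assert sequence_identity(viterbi(a, b, hmm_params), a, b) == 0.0

    def test_ratio_counts_all_columns(self):
        # 10-column path: 7 ALN columns (4 identical) + 3 insert columns
        x = RnaSequence("x", "ACGUAAAGGG")
        y = RnaSequence("y", "ACGUCCC")
        path = [("ALN", t, t) for t in range(1, 8)]
        path += [("INS1", i, 7) for i in range(8, 11)]
        assert sequence_identity(path, x, y) == 4 / 10


class TestConstraintSets:
    def test_threshold_extremes(self, hmm_params):
        rng = np.random.default_rng(16)
        x = random_sequence(rng, 8, "x")
        y = random_sequence(rng, 6, "y")
        cm = coincidence(x, y, hmm_params)
        everything = constraint_sets(cm, 0.0)
        # tau = 0 keeps every strictly positive entry; all entries here are > 0
        assert everything.mask.all()
        assert everything.d == 6.0
        with pytest.raises(ValueError):
            constraint_sets(cm, 1.0)

    def test_matches_naive_full_scan(self, hmm_params):
        rng = np.random.default_rng(17)
        x = random_sequence(rng, 10, "x")
        y = random_sequence(rng, 9, "y")
        cm = coincidence(x, y, hmm_params)
        cs = constraint_sets(cm, 0.5)
        for i in range(1, 11):
            expected = {k for k in range(1, 10) if cm.probs[i - 1, k - 1] > 0.5}
            assert set(cs.partners(i)) == expected
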