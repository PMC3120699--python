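import math

import numpy as np
import pytest

from conftest import random_ext, random_sequence
from turbofold.io_formats import RnaSequence
from turbofold.partition import (
    brute_force_pair_probs,
    enumerate_structures,
    modified_partition,
    unpaired_probabilities,
)


class TestDegenerateCases:
    def test_unpairable_sequence_has_only_empty_structure(self):
        seq = RnaSequence("s", "AAAA")
        res = modified_partition(seq)
        assert res.z == pytest.approx(1.0)
        assert np.all(res.matrix.probs == 0.0)
        assert len(enumerate_structures(seq)) == 1

    def test_neutral_ext_equals_plain_partition(self):
        rng = np.random.default_rng(21)
        seq = random_sequence(rng, 30, "s")
        plain = modified_partition(seq, None, gamma=0.0)
        ones = modified_partition(seq, np.ones((30, 30)), gamma=1.2 * 0.61633)
        assert np.array_equal(plain.matrix.probs, ones.matrix.probs)
        assert plain.log_z == pytest.approx(ones.log_z, abs=1e-12)

    def test_gamma_zero_ignores_extrinsic(self):
        rng = np.random.default_rng(22)
        seq = random_sequence(rng, 25, "s")
        ref = modified_partition(seq, None, gamma=0.0)
        res = modified_partition(seq, random_ext(rng, 25), gamma=0.0)
        assert np.array_equal(ref.matrix.probs, res.matrix.probs)

    def test_negative_gamma_and_bad_shapes_rejected(self):
        seq = RnaSequence("s", "GGGAAACCC")
        with pytest.raises(ValueError):
            modified_partition(seq, None, gamma=-0.1)
        with pytest.raises(ValueError):
            modified_partition(seq, np.ones((3, 3)), gamma=0.1)


class TestOracleAgreement:
    def test_matches_enumeration_on_random_instances(self, energy_params):
        rng = np.random.default_rng(23)
        gammas = [0.0, 0.3 * energy_params.RT, 1.2 * energy_params.RT]
        for trial in range(24):
            n = int(rng.integers(8, 19))
            seq = random_sequence(rng, n, f"t{trial}")
            ext = random_ext(rng, n)
            gamma = gammas[trial % 3]
            dp = modified_partition(seq, ext, gamma, energy_params)
            bf = brute_force_pair_probs(seq, ext, gamma, energy_params)
            assert dp.log_z == pytest.approx(bf.log_z, abs=1e-9)
            denom = np.maximum(bf.matrix.probs, 1e-12)
            rel = np.abs(dp.matrix.probs - bf.matrix.probs) / denom
            rel[bf.matrix.probs < 1e-12] = np.abs(
                dp.matrix.probs[bf.matrix.probs < 1e-12]
            )
            assert rel.max() < 1e-9

    def test_structure_count_cross_check(self, energy_params):
        # independent recursive matching counter
        seq = RnaSequence("s", "GGGAAACCC")

        def count(residues: str) -> int:
            from turbofold.energy_model import CANONICAL, NT_INDEX

            codes = [NT_INDEX[c] for c in residues]
            minh = energy_params.min_hairpin
            from functools import lru_cache

            @lru_cache(maxsize=None)
            def c(i, j):
                if j - i < minh + 1:
                    return 1
                total = c(i + 1, j)
                for k in range(i + minh + 1, j + 1):
                    if (codes[i], codes[k]) in CANONICAL:
                        total += c(i + 1, k - 1) * c(k + 1, j)
                return total

            return c(0, len(residues) - 1)

        assert len(enumerate_structures(seq)) == count(seq.residues)

    def test_enumeration_guard(self):
        rng = np.random.default_rng(24)
        with pytest.raises(ValueError):
            enumerate_structures(random_sequence(rng, 21, "big"))


class TestProbabilityInvariants:
    def test_conservation_and_unpaired_vector(self, energy_params):
        rng = np.random.default_rng(25)
        for _ in range(5):
            n = int(rng.integers(20, 60))
            seq = random_sequence(rng, n, "s")
            res = modified_partition(seq, random_ext(rng, n), 0.3 * energy_params.RT)
            row = res.matrix.row_sums()
            assert np.all(row <= 1 + 1e-9)
            q = unpaired_probabilities(res.matrix)
            assert np.max(np.abs(row + q - 1.0)) < 1e-9

    def test_unpaired_probability_direct_cases(self):
        from turbofold.partition import PairProbabilityMatrix

        m = PairProbabilityMatrix(np.zeros((5, 5)))
        assert np.all(unpaired_probabilities(m) == 1.0)
        probs = np.zeros((5, 5))
        probs[0, 3] = 0.3
        q = unpaired_probabilities(PairProbabilityMatrix(probs))
        assert q[0] == pytest.approx(0.7)
        assert q[3] == pytest.approx(0.7)

    def test_monotone_response_to_extrinsic_support(self, energy_params):
        rng = np.random.default_rng(26)
        seq = random_sequence(rng, 16, "s")
        # pick a canonical pair with nonzero probability
        base = modified_partition(seq, None, 0.3 * energy_params.RT)
        i, j = np.unravel_index(np.argmax(base.matrix.probs), base.matrix.probs.shape)
        if base.matrix.probs[i, j] == 0:
            pytest.skip("no pairable positions in this draw")
        prev = -1.0
        for level in [0.05, 0.3, 0.7, 1.0]:
            ext = np.full((16, 16), 0.5)
            ext[i, j] = level
            p = modified_partition(seq, ext, 0.3 * energy_params.RT).matrix.probs[i, j]
            assert p >= prev
            prev = p

    def test_long_sequence_scaling_stability(self):
        rng = np.random.default_rng(27)
        seq = random_sequence(rng, 500, "long")
        res = modified_partition(seq)
        assert np.isfinite(res.log_z)
        assert np.all(np.isfinite(res.matrix.probs))
        assert np.all(res.matrix.row_sums() <= 1 + 1e-9)
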