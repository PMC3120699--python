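import numpy as np
import pytest

from turbofold.io_formats import RnaSequence
from turbofold.partition import modified_partition
from turbofold.synthetic_families import default_family_spec, generate_family
from turbofold.turbofold_core import TurboConfig, iteration_trace, run_turbofold


@pytest.fixture(scope="module")
def family():
    return generate_family(default_family_spec(k=4, target_identity=0.5, seed=5))


class TestReductionIdentities:
    def test_eta_zero_equals_single_sequence_partition(self, family, energy_params):
        seqs, _ = family
        res = run_turbofold(seqs, TurboConfig(iterations=0))
        for s in seqs:
            single = modified_partition(s, None, 0.3 * energy_params.RT, energy_params)
            assert np.array_equal(res.matrices[s.id].probs, single.matrix.probs)

    def test_gamma_zero_equals_single_sequence_partition(self, family, energy_params):
        seqs, _ = family
        res = run_turbofold(seqs, TurboConfig(gamma=0.0, iterations=2))
        for s in seqs:
            single = modified_partition(s, None, 0.0, energy_params)
            assert np.array_equal(res.matrices[s.id].probs, single.matrix.probs)

    def test_identical_inputs_stay_neutral(self, energy_params):
        base = "GGCAGGCCAUGCGGCUUCGAGCCGC" * 2
        seqs = [RnaSequence(f"s{i}", base) for i in range(3)]
        res = run_turbofold(seqs, TurboConfig(iterations=2))
        single = modified_partition(
            RnaSequence("x", base), None, 0.3 * energy_params.RT, energy_params
        )
        for s in seqs:
            assert res.identities[("s0", "s1")] == 1.0
            assert np.array_equal(res.matrices[s.id].probs, single.matrix.probs)

    def test_single_sequence_warns_and_degenerates(self, energy_params):
        seq = RnaSequence("only", "GGGAAAACCC")
        with pytest.warns(UserWarning):
            res = run_turbofold([seq], TurboConfig(iterations=2))
        single = modified_partition(seq, None, 0.3 * energy_params.RT, energy_params)
        assert np.array_equal(res.matrices["only"].probs, single.matrix.probs)


class TestDeterminism:
    def test_thread_count_does_not_change_results(self, family):
        seqs, _ = family
        res1 = run_turbofold(seqs, TurboConfig(iterations=2, threads=1))
        res4 = run_turbofold(seqs, TurboConfig(iterations=2, threads=4))
        for s in seqs:
            assert np.array_equal(res1.matrices[s.id].probs, res4.matrices[s.id].probs)

    def test_history_length_is_eta_plus_one(self, family):
        seqs, _ = family
        res = run_turbofold(seqs, TurboConfig(iterations=2))
        assert len(res.history) == 3


class TestIterationTrace:
    def test_trace_shape_and_zero_iteration_row(self, family):
        seqs, known = family
        res = run_turbofold(seqs, TurboConfig(iterations=2))
        tr = iteration_trace(res, known)
        assert list(tr["t"]) == [0, 1, 2]
        assert set(tr.columns) >= {"t", "sensitivity", "ppv", "f_measure"}
        res0 = run_turbofold(seqs, TurboConfig(iterations=0))
        assert len(iteration_trace(res0, known)) == 1

    def test_trace_requires_history(self, family):
        seqs, known = family
        res = run_turbofold(seqs, TurboConfig(iterations=1, keep_history=False))
        with pytest.raises(ValueError):
            iteration_trace(res, known)

    def test_refinement_improves_accuracy_on_average(self):
        # conserved-structure families at ~50% identity: iteration 3 should
        # beat iteration 0 on mean F-measure over a handful of seeds
        f0, f3 = [], []
        for seed in range(3):
            seqs, known = generate_family(
                default_family_spec(k=5, target_identity=0.5, seed=100 + seed)
            )
            res = run_turbofold(seqs, TurboConfig(iterations=3))
            tr = iteration_trace(res, known)
            f0.append(tr["f_measure"].iloc[0])
            f3.append(tr["f_measure"].iloc[-1])
        assert np.mean(f3) >= np.mean(f0)


class TestValidation:
    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_turbofold([], TurboConfig())

    def test_duplicate_ids_rejected(self):
        seqs = [RnaSequence("a", "GGGAAACCC"), RnaSequence("a", "GGGAAACCC")]
        with pytest.raises(ValueError):
            run_turbofold(seqs, TurboConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TurboConfig(gamma=-1)
        with pytest.raises(ValueError):
            TurboConfig(iterations=-1)
        with pytest.raises(ValueError):
            TurboConfig(mode="bogus")
        with pytest.raises(ValueError):
            TurboConfig(threads=0)
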