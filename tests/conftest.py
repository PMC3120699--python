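import numpy as np
import pytest

from turbofold.alignment_hmm import default_hmm_params
from turbofold.energy_model import default_energy_params
from turbofold.io_formats import RnaSequence

NUCS = np.array(list("ACGU"))


def random_sequence(rng: np.random.Generator, n: int, seq_id: str = "r") -> RnaSequence:
    return RnaSequence(seq_id, "".join(rng.choice(NUCS, n)))


def random_ext(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random valid extrinsic matrix: upper triangle in [0, 1]."""
    return np.triu(rng.random((n, n)), 1)


@pytest.fixture(scope="session")
def energy_params():
    return default_energy_params()


@pytest.fixture(scope="session")
def hmm_params():
    return default_hmm_params()
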