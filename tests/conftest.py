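import numpy as np
import pytest

from ppiboost.seqio import AMINO_ACIDS, ProteinRecord
from ppiboost.synthetic import SynthConfig, generate_dataset


def random_protein(rng, length, pid="p"):
    return ProteinRecord(pid, "".join(rng.choice(list(AMINO_ACIDS), size=length)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully learnable synthetic dataset shared across tests."""
    return generate_dataset(
        SynthConfig(n_proteins=30, length_range=(50, 90), n_pairs=80, seed=11)
    )


@pytest.fixture(scope="session")
def protein60(rng):
    return random_protein(rng, 60, "fix60")
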