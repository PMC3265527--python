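import numpy as np
import pytest

from mirevo.core_seq import MiRNA
from mirevo.duplex import EnergyModel


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_mirna():
    # 22-nt miRNA with a mixed-composition seed
    return MiRNA("mir-toy", "UGAGGUAGUAGGUUGUAUAGUU")


def random_rna(rng, length, alphabet="ACGU"):
    return "".join(alphabet[b] for b in rng.integers(len(alphabet), size=length))
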