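import numpy as np
import pytest

from plantppi.io_formats import ProteinRecord
from plantppi.synthetic import SynthConfig, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared by read-only tests."""
    cfg = SynthConfig(n_proteins=20, length_range=(30, 60), n_pos=30, n_neg=30, seed=3)
    return gen_dataset(cfg)


@pytest.fixture
def toy_record():
    return ProteinRecord(id="toy1", sequence="MKVLATGFF")
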