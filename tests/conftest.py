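import numpy as np
import pytest

from ddgfuse import AAPTable, ProteinSequence, SimConfig, gen_dataset


@pytest.fixture(scope="session")
def aap_table() -> AAPTable:
    return AAPTable.default()


@pytest.fixture(scope="session")
def small_study():
    """A small planted-truth dataset shared by fast integration tests."""
    return gen_dataset(SimConfig(seed=11, n_proteins=8, n_variants=60,
                                 length_range=(30, 60), embed_dim=16))


@pytest.fixture()
def toy_sequence() -> ProteinSequence:
    return ProteinSequence("toy", "MAVKLFGDES")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
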