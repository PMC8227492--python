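import numpy as np
import pytest

from mirdupscreen.io_formats import SequenceRecord
from mirdupscreen.signature import MatureMiRNA
from mirdupscreen.synthetic import MIR31_3P, MIR31_5P, SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def mir31_5p() -> MatureMiRNA:
    return MatureMiRNA.from_name("hsa-miR-31-5p", SequenceRecord("hsa-miR-31-5p", "", MIR31_5P))


@pytest.fixture(scope="session")
def mir31_3p() -> MatureMiRNA:
    return MatureMiRNA.from_name("hsa-miR-31-3p", SequenceRecord("hsa-miR-31-3p", "", MIR31_3P))


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down cohort for fast unit tests (not the study-sized default)."""
    return SimConfig(
        n_tumor=150,
        n_normal=30,
        n_mirnas=60,
        n_duplex_up=4,
        n_genes=60,
        n_true_targets=10,
        utr_length=600,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
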