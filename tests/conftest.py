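import numpy as np
import pytest

from otupick import (
    Concatesome,
    ReferenceSet,
    build_concatesome,
    build_fm_index,
    SimulationSpec,
    simulate,
)


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_ref_concatesome():
    refs = ReferenceSet((("A", "ACGT"), ("B", "GGCC")))
    return build_concatesome(refs)


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free amplicon simulation: 5 references, 3 samples, 100 reads each."""
    return simulate(SimulationSpec(seed=7))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same study design with 2% per-base substitution error."""
    return simulate(SimulationSpec(seed=11, substitution_rate=0.02))


@pytest.fixture(scope="session")
def clean_concatesome(clean_dataset):
    return build_concatesome(clean_dataset.references)


@pytest.fixture(scope="session")
def clean_fm_index(clean_concatesome):
    return build_fm_index(clean_concatesome)
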