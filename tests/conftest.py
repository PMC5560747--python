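import numpy as np
import pytest

from kronaff.io_formats import STANDARD_AMINO_ACIDS, load_blosum
from kronaff.protein_kernels import AlignmentParams
from kronaff.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def blosum50():
    return load_blosum("BLOSUM50")


@pytest.fixture(scope="session")
def align_params(blosum50):
    return AlignmentParams(substitution=blosum50)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def random_sequence(rng, length):
    return "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=length))


@pytest.fixture(scope="session")
def small_dataset():
    """A 12 x 8 synthetic instance shared by CV and model tests."""
    return generate(
        SyntheticConfig(n_drugs=12, n_proteins=8, missing_frac=0.15, seed=11)
    )
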