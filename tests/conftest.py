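import numpy as np
import pytest

from bekit.simulate import DoseModel, EditorProfile, generate_screen

NUCS = "ACGT"


def random_dna(rng, n):
    return "".join(rng.choice(list(NUCS), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_screen():
    """A 150-site simulated screen with ground truth, shared across tests."""
    ds, truth = generate_screen(
        150, EditorProfile.abe8e_like(), DoseModel.mrna_like(),
        depth=3000, replicates=2, noise_sd=0.2, seed=7,
    )
    return ds, truth
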