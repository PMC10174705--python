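import numpy as np
import pytest

from acrscreen.io import AA_ORDER, PSSM
from acrscreen.synthetic import SynthConfig, generate


def random_pssm(rng: np.random.Generator, length: int) -> PSSM:
    """Integer-score PSSM over a random standard-residue sequence."""
    seq = "".join(AA_ORDER[i] for i in rng.integers(20, size=length))
    scores = rng.integers(-10, 11, size=(length, 20)).astype(float)
    return PSSM(sequence=seq, scores=scores)


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic dataset shared across tests (fast to featurize)."""
    return generate(
        SynthConfig(
            n_pos=24,
            n_neg=24,
            length_range=(50, 120),
            embedding_dim=64,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
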