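import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytofeat import GeneratorConfig, ProteinSequence
from cytofeat._alphabet import ALPHA_ORDER
from cytofeat.synthetic import gen_objects

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def random_sequence(rng: np.random.Generator, length: int, seq_id: str = "s") -> ProteinSequence:
    residues = "".join(ALPHA_ORDER[i] for i in rng.integers(0, 20, size=length))
    return ProteinSequence(id=seq_id, residues=residues)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180811)


@pytest.fixture(scope="session")
def random_sequences():
    """200 random sequences of length 20-80 for oracle-equivalence tests."""
    gen = np.random.default_rng(42)
    return [
        random_sequence(gen, int(gen.integers(20, 81)), f"r{i:03d}")
        for i in range(200)
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """A small balanced synthetic dataset with clear class separation."""
    return gen_objects(GeneratorConfig(n_pos=15, n_neg=15, seed=7))


@pytest.fixture()
def worked_structure():
    """The 13-residue secondary-structure worked example with uniform SPM."""
    from cytofeat import StructurePrediction

    return StructurePrediction(
        "worked", "EEEEHHEEHHHCC", np.full((13, 3), 1.0 / 3.0)
    )
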