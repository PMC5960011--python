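import numpy as np
import pytest

from bellcog import (
    MEASUREMENTS,
    JointProbabilityTable,
    MeasurementScheme,
    load_fixture,
)


@pytest.fixture(scope="session")
def eq2_table() -> JointProbabilityTable:
    """The raw 85-participant windrose table."""
    return load_fixture("wind_eq2")


@pytest.fixture(scope="session")
def eq5_table() -> JointProbabilityTable:
    """The printed 180-degree-symmetrized table."""
    return load_fixture("wind_eq5")


@pytest.fixture(scope="session")
def eq10_table() -> JointProbabilityTable:
    """The printed octahedrally symmetrized table."""
    return load_fixture("wind_eq10")


@pytest.fixture
def uniform_table() -> JointProbabilityTable:
    return JointProbabilityTable.uniform()


def make_random_table(rng: np.random.Generator) -> JointProbabilityTable:
    """A normalized random table (Dirichlet cells per block)."""
    return JointProbabilityTable(
        p={m: rng.dirichlet(np.ones(4)).reshape(2, 2) for m in MEASUREMENTS},
        scheme=MeasurementScheme.windrose(),
    )


@pytest.fixture
def random_tables():
    rng = np.random.default_rng(20260930)
    return [make_random_table(rng) for _ in range(50)]
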