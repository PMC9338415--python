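import numpy as np
import pytest

from digistress.io import load_table2
from digistress.simulate import simulate_cohort, table2_default_spec


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def small_cohort():
    """Full event-level cohort, 20 + 20 participants, fixed seed."""
    spec = table2_default_spec(n_stress=20, n_control=20, seed=42)
    return simulate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
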