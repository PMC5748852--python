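import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 12/12/12 cohort shared by cohort-level tests."""
    import pulsetrace as pt

    config = pt.CohortConfig(
        n_cells_per_subset={"HEC": 12, "BC": 12, "IAHC": 12}, seed=42
    )
    return pt.simulate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default study conditions (30 cells per subset)."""
    import pulsetrace as pt

    return pt.simulate_cohort(pt.CohortConfig(seed=7))
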