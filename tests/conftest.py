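import pytest

from strat4concord import AssayConfig, CohortSpec, generate


@pytest.fixture(scope="session")
def assay():
    return AssayConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort, shared across tests."""
    return generate(CohortSpec(n_samples=523, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    return generate(CohortSpec(n_samples=200, seed=5))
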