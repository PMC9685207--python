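import pytest

from pdxpower import DesignSpec, ModelParams, COHORT_MEDIANS


@pytest.fixture(scope="session")
def medians() -> ModelParams:
    """Aggregate cohort medians — the package defaults."""
    return COHORT_MEDIANS


@pytest.fixture(scope="session")
def design_4wk() -> DesignSpec:
    """Canonical 4-week twice-weekly 1x1x1 design at alpha = .05."""
    return DesignSpec(days=(0, 4, 7, 11, 14, 18, 21, 25), n_per_group=1, alpha=0.05)


@pytest.fixture
def noise_free(medians) -> ModelParams:
    """Degenerate parameters: no residual noise, no random effects."""
    return medians.with_(sigma=0.0, tau0=0.0, tau1=0.0, tau01=0.0)
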