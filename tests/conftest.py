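import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from trialscape import (  # noqa: E402
    GeneratorConfig,
    apply_filters,
    generate_registry,
    load_phase3_assignments,
    load_phase3_compendium,
)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def snapshot(default_config):
    """One generated default-scale snapshot (481 records incl. decoys)."""
    return generate_registry(default_config)


@pytest.fixture(scope="session")
def curated(snapshot):
    """The 430 relevant trials surviving the default filters."""
    kept, _ = apply_filters(snapshot)
    return kept


@pytest.fixture(scope="session")
def compendium():
    """The packaged 37-trial late-phase compendium fixture."""
    return load_phase3_compendium()


@pytest.fixture(scope="session")
def compendium_assignments():
    return load_phase3_assignments()
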