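from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from lipidkit.registry import POSITIVE_ADDUCTS
from lipidkit.simulate import default_registry

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def registry():
    """The default ~36-species synthetic registry."""
    return default_registry()


@pytest.fixture(scope="session")
def proton_adduct():
    return POSITIVE_ADDUCTS[0]


@pytest.fixture(scope="session")
def registry_fixture_path() -> Path:
    """Shipped synthetic registry TSV (generated from the class formula rules)."""
    return DATA_DIR / "registry_fixture.tsv"
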