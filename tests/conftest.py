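import pytest
from hypothesis import HealthCheck, settings

from tracerdiff.compounds import load_compounds

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compound_table():
    return load_compounds()
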