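import pytest
from hypothesis import HealthCheck, settings

from phagemap import synthetic_reference
from phagemap.antigen import ANTIGEN_LOCAL, ResidueSpan

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    """A 438-residue synthetic fusion antigen (1314 bp CDS, offset 183)."""
    return synthetic_reference(seed=0)


@pytest.fixture(scope="session")
def epitope_sets():
    """Two required stretches in antigen-local numbering (140-154, 248-254)."""
    return [ResidueSpan(140, 154, ANTIGEN_LOCAL),
            ResidueSpan(248, 254, ANTIGEN_LOCAL)]
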