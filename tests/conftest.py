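import pytest
from hypothesis import HealthCheck, settings

from srnakit import novel as nov
from srnakit.synthetic import SimConfig, simulate_library

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lib42():
    """The default seed-42 synthetic study bundle."""
    return simulate_library(SimConfig())


@pytest.fixture(scope="session")
def cands42(lib42):
    """Novel-candidate discovery on the seed-42 bundle (expensive; shared)."""
    unannotated = [
        r for r in lib42.reads if lib42.truth.annotation_of(r.seq) == "unannotated"
    ]
    known = {k.seq for k in lib42.known}
    return nov.discover_novel(unannotated, lib42.transcripts, known)
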