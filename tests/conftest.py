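import pytest

from casedit import simulate as sim


@pytest.fixture(scope="session")
def demo_site():
    """Dual-compatible demonstration target (engineered core, -4 base A)."""
    return sim.make_demo_site("SpCas9", seed=0)


@pytest.fixture(scope="session")
def demo_site_sa():
    return sim.make_demo_site("SaCas9", seed=0)


@pytest.fixture(scope="session")
def profiles():
    return sim.load_profiles()
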