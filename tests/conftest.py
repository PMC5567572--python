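import pytest

from pmoca import SyntheticFamilyConfig, generate_family, published_primers


@pytest.fixture(scope="session")
def primer_set():
    """The packaged pmoC374 / pmoA189 / pmoA344 set, keyed by name."""
    return {p.name: p for p in published_primers()}


@pytest.fixture(scope="session")
def family():
    """One default synthetic operon family (24 records, 3 lineages)."""
    return generate_family(SyntheticFamilyConfig(seed=7))


@pytest.fixture(scope="session")
def family_factory():
    def make(seed=0, **overrides):
        return generate_family(SyntheticFamilyConfig(seed=seed, **overrides))

    return make
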