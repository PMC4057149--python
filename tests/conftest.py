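import pytest

from cescan import UniverseSpec, make_cerna_universe, make_mirna_panel


@pytest.fixture(scope="session")
def panel8():
    """Eight synthetic miRNAs with well-separated seeds."""
    return make_mirna_panel(8, rng_seed=20240101)


@pytest.fixture(scope="session")
def small_universe():
    """A fully sequenced 30-miRNA / 6-lncRNA / 8-mRNA universe."""
    return make_cerna_universe(UniverseSpec(rng_seed=42))
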