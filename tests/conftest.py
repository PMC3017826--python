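import pytest

from fyvescan import motif_engine as me
from fyvescan import synthetic_data as sd


@pytest.fixture(scope="session")
def classic_domain():
    """A zero-mutation classic-signature FYVE domain plus its truth."""
    return sd.make_fyve_domain("classic", seed=1)


@pytest.fixture(scope="session")
def variant_domain():
    """A zero-mutation plant-variant FYVE domain plus its truth."""
    return sd.make_fyve_domain("variant", seed=1)


@pytest.fixture(scope="session")
def classic_scaffold(classic_domain):
    seq, _ = classic_domain
    hits = me.find_fyve_scaffold(seq)
    assert len(hits) == 1
    return hits[0]


@pytest.fixture(scope="session")
def small_proteome():
    """Zero-mutation proteome with the default 2/2/1/1/9 class census."""
    return sd.make_proteome(sd.SyntheticSpec(seed=5))
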