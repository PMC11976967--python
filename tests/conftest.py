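import pytest

from pcfkit import reference, simulate


@pytest.fixture(scope="session")
def standard_proteome_pair():
    """The standard planted-homolog fixture: 8 homolog pairs (incl. three
    pentahemes and one motif-free pair), 12 decoys, 10% mutation, seed 42."""
    spec = simulate.ProteomeSimSpec(seed=42)
    return simulate.gen_proteome_pair(spec)


@pytest.fixture(scope="session")
def gs_regions():
    return reference.edx_regions("GS")


@pytest.fixture(scope="session")
def rb_regions():
    return reference.edx_regions("RB")
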