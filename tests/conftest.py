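import pytest

from g4switch import make_artificial_g4, make_ds_g4


@pytest.fixture(scope="session")
def artg4():
    """Artificial long-central-loop G4: tract 3, single-U loops 1/3, 13-nt loop 2."""
    return make_artificial_g4(tract_len=3, loop2_len=13, flank_len=15, seed=1)


@pytest.fixture(scope="session")
def dsg4():
    """Double-stranded G4: upstream arm sequesters loop 2 + 5 tract guanines."""
    return make_ds_g4(tract_len=3, loop2_len=13, flank_len=15, sequestered_g=5, seed=1)
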