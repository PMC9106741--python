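import numpy as np
import pytest

from hashladder.ladder import HashSpecies, LadderSpec, make_serial_ladder


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ladder():
    """Six-species ten-fold ladder with fixed barcodes, 1e5 nuclei."""
    barcodes = [
        "AAAAACCCCC",
        "GGGGGTTTTT",
        "ACACACACAC",
        "GTGTGTGTGT",
        "AATTAATTAA",
        "CCGGCCGGCC",
    ]
    species = [
        HashSpecies(f"L{k}", barcodes[k], 1e-4 * 10**k) for k in range(6)
    ]
    return LadderSpec(species, n_cells_per_condition=100_000)


@pytest.fixture
def ladder48():
    from hashladder.synthetic import default_ladder_48

    return default_ladder_48()
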