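import numpy as np
import pytest

from pirnakit.synth import (
    LibraryConfig,
    SpeciesConfig,
    generate_species,
    simulate_small_rna_libraries,
)


@pytest.fixture(scope="session")
def ctype_bundle():
    """Clustered-organization species with 220 planted loci."""
    return generate_species(
        SpeciesConfig(mode="C-type", n_pirna_loci=220, seed=11)
    )


@pytest.fixture(scope="session")
def ptype_bundle():
    """Dispersed, intron-resident organization with 220 planted loci."""
    return generate_species(
        SpeciesConfig(mode="P-type", n_pirna_loci=220, seed=11)
    )


@pytest.fixture(scope="session")
def ctype_library(ctype_bundle):
    return simulate_small_rna_libraries(ctype_bundle, LibraryConfig(seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
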