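import numpy as np
import pytest

from mutscan import library_design as ld
from mutscan import read_calling as rc
from mutscan import simulate as sim


@pytest.fixture(scope="session")
def gene_model():
    """A 120-codon synthetic gene whose 80-codon domain spans codons 11-90."""
    rng = np.random.default_rng(1234)
    cds = sim.random_cds(120, rng)
    return ld.make_gene_model("geneA", cds, (11, 90))


@pytest.fixture(scope="session")
def tiles(gene_model):
    return ld.tile_domain(gene_model)


@pytest.fixture(scope="session")
def designs(gene_model):
    _, d = ld.design_library(gene_model)
    return d


@pytest.fixture(scope="session")
def design_frame(designs):
    return ld.designs_to_frame(designs)


@pytest.fixture(scope="session")
def tile_ref(tiles):
    return rc.TileReference.from_tile(tiles[0])
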