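import numpy as np
import pytest

from trnacurate.io_formats import load_standard_set
from trnacurate.synthetic_fixtures import (
    ArraySpec,
    FixtureSpec,
    IntegrationSpec,
    MaskSpec,
    generate,
    make_canonical_gene,
)


@pytest.fixture(scope="session")
def standard():
    return load_standard_set()


@pytest.fixture(scope="session")
def canonical_gene():
    """A fixed, reproducible canonical Gln-TTG gene sequence."""
    rng = np.random.default_rng(42)
    return make_canonical_gene(rng, "Gln", "TTG")


@pytest.fixture(scope="session")
def event_fixture():
    """One genome with a planted integration, CRISPR array and N-mask."""
    spec = FixtureSpec(
        seed=11, genome_length=120_000, n_canonical=46,
        integrations=(IntegrationSpec(target_index=0),),
        arrays=(ArraySpec(n_repeats=12, embed_trna_fragment=True,
                          fragment_source_index=1),),
        maskings=(MaskSpec(gene_index=2),),
    )
    return generate(spec)


@pytest.fixture(scope="session")
def plain_fixture():
    """A genome with planted canonical genes only (negative control)."""
    return generate(FixtureSpec(seed=13, genome_length=60_000,
                                n_canonical=12))
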