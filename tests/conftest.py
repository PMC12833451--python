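import logging

import pytest

from spallm import (
    EmbeddingSpec,
    EncoderConfig,
    TissueSpec,
    gene_programs,
    make_embedding_table,
    make_tissue,
)

logging.getLogger("spallm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_spec():
    """A 10x10 five-band tissue small enough for fast pipeline runs."""
    return TissueSpec(rows=10, cols=10, n_domains=5, n_genes=60, program_size=10, seed=7)


@pytest.fixture(scope="session")
def small_tissue(small_spec):
    return make_tissue(small_spec)


@pytest.fixture(scope="session")
def small_table(small_spec):
    return make_embedding_table(
        EmbeddingSpec(dim=32, seed=7), gene_programs(small_spec)
    )


@pytest.fixture(scope="session")
def fast_encoder():
    """Scaled-down encoder settings for unit tests."""
    return EncoderConfig(epochs=40, d_hidden=32, d_ST=16, seed=0)


@pytest.fixture(scope="session")
def default_tissue():
    """The default 40x40 five-domain tissue used by system-level checks."""
    return make_tissue(TissueSpec(seed=1))


@pytest.fixture(scope="session")
def default_table():
    return make_embedding_table(EmbeddingSpec(seed=1), gene_programs(TissueSpec(seed=1)))
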