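import pytest

from retroinvade import synthetic


@pytest.fixture(scope="session")
def library():
    """Small consensus library: 3 LTR-shaped families with an internal
    poly-A track, 3 single-copy genes."""
    return synthetic.make_demo_library(
        n_families=3, family_length=900, ltr_length=120, n_genes=3,
        gene_length=700, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_library():
    """Even smaller library for exhaustive-oracle comparisons."""
    return synthetic.make_demo_library(
        n_families=2, family_length=600, ltr_length=80, n_genes=1,
        gene_length=500, seed=7,
    )
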