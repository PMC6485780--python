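import pytest

from taxogen.synthetic import simulate_ancestor


@pytest.fixture(scope="session")
def small_ancestor():
    """A ~25 kb annotated genome shared by the integration tests."""
    return simulate_ancestor(n_genes=40, gene_len_mean=300,
                             intergenic_mean=80, seed=11)


@pytest.fixture(scope="session")
def tiny_ancestor():
    return simulate_ancestor(n_genes=12, gene_len_mean=240,
                             intergenic_mean=60, seed=23)
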