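import pytest

from xdamp import build_genome


@pytest.fixture(scope="session")
def genome150():
    """Standard allelic-panel genome: 150 X genes, 300 autosomal, 2 SNPs/gene."""
    return build_genome(150, 300, 1.5e8, 1.5e8, snps_per_gene=2, seed=1)


@pytest.fixture(scope="session")
def tiny_genome():
    """Small genome for fast unit tests."""
    return build_genome(10, 10, 1e6, 1e6, snps_per_gene=2, seed=1, gene_length=5000)
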