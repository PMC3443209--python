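import pytest

from tlrpop.datasets import founder_genotype_fixture, robin_snp_panel


@pytest.fixture(scope="session")
def snp_panel():
    """(Locus, sites) pairs for the nine-locus robin amplicon panel."""
    return robin_snp_panel()


@pytest.fixture(scope="session")
def founder_fixture():
    """Variant-level genotypes of the 12 founders at 7 polymorphic loci."""
    return founder_genotype_fixture()
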