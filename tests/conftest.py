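import pytest

from gwasprio.datasets import (
    load_ec_gene_report,
    load_replication_genotype_counts,
    load_wtccc_genotype_counts,
)


@pytest.fixture(scope="session")
def ec_gene_report():
    """Best SNP per gene body for the 71 endothelial-specific genes."""
    return load_ec_gene_report()


@pytest.fixture(scope="session")
def replication_tables():
    """Six replication-stage genotype count tables keyed by snp_id."""
    return {t.snp_id: t for t in load_replication_genotype_counts()}


@pytest.fixture(scope="session")
def wtccc_tables():
    """The same six SNPs' genotype counts in the original scan."""
    return {t.snp_id: t for t in load_wtccc_genotype_counts()}
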