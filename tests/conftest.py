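import pytest

from acmgrules.evidence_io import config_for_gene
from acmgrules.fixtures import fixture_gene_configs


@pytest.fixture(scope="session")
def configs():
    return fixture_gene_configs()


@pytest.fixture()
def general_cfg(configs):
    return config_for_gene(configs, "GENE1")


@pytest.fixture(scope="session")
def assay_table():
    from acmgrules.codon_context import load_assay_table

    return load_assay_table()


@pytest.fixture(scope="session")
def exclusion_rules():
    from acmgrules.combiner import load_exclusion_rules

    return load_exclusion_rules()
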