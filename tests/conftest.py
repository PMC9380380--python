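import pytest

from cpclassify.knowledgebase import (
    load_bundled_tables,
    load_gene_configs,
    load_gene_evidence,
    load_reclassification_set,
)


@pytest.fixture(scope="session")
def gold_standard_records():
    """The combined gold-standard calibration set (GoF + GoP + LoF tables)."""
    return (load_bundled_tables("T3") + load_bundled_tables("T4")
            + load_bundled_tables("T5"))


@pytest.fixture(scope="session")
def gene_configs():
    return load_gene_configs()


@pytest.fixture(scope="session")
def gene_evidence():
    return load_gene_evidence()


@pytest.fixture(scope="session")
def reclassification_records():
    return {rec.key: rec for rec in load_reclassification_set()}
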