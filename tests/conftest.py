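import pytest

from phantombridge import default_mapping, load_catalog


@pytest.fixture(scope="session")
def ce_catalog():
    return load_catalog("CE")


@pytest.fixture(scope="session")
def icrp_catalog():
    return load_catalog("ICRP")


@pytest.fixture(scope="session")
def mapping_table(ce_catalog, icrp_catalog):
    return default_mapping(ce_catalog, icrp_catalog)
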