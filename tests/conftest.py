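import pytest

from abyssminer.catalog import load_catalog
from abyssminer.synthetic_data import GeneratorConfig, generate_catalog_proteins

# the suite uses shorter reference proteins and smaller backgrounds than
# the generator defaults so the alignment-heavy paths stay quick; the
# properties under test do not depend on sequence length


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(seed=1, catalog_protein_lengths=(90, 130), background_gene_count=16)


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return generate_catalog_proteins(small_config)


@pytest.fixture(scope="session")
def fixture_catalog():
    return load_catalog()
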