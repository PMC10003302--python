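import pytest

from cdcurate import reference
from cdcurate.cf_threshold import PrevalenceModel


@pytest.fixture(scope="session")
def panel():
    return reference.gene_panel()


@pytest.fixture(scope="session")
def policy(panel):
    return reference.default_policy(panel)


@pytest.fixture(scope="session")
def prevalence():
    return PrevalenceModel()


@pytest.fixture(scope="session")
def literature():
    return reference.synthetic_literature_reconstruction()


@pytest.fixture(scope="session")
def pop_freqs():
    return reference.reference_population_frequencies()


@pytest.fixture(scope="session")
def cohort_variants():
    return reference.cohort_variant_table()
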