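import pytest

from col4dx.config import default_config
from col4dx.io import load_fixture_bundle


@pytest.fixture(scope="session")
def bundle():
    return load_fixture_bundle()


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def fixture_records(bundle, config):
    """All 38 reference variants as rule-engine records, keyed by variant."""
    return {r.variant_key: r for r in bundle.variant_records(config)}


@pytest.fixture(scope="session")
def reference_run(bundle, config):
    """Full fixture cohort run: (classifications, summary, diagnoses)."""
    return bundle.run_reference_cohort(config)
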