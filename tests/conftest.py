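import numpy as np
import pytest

from cpipred.curation import CurationConfig, curate
from cpipred.synthetic import GeneratorConfig, golden_curation_fixture, make_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A desk-size benchmark: 80 compounds x 12 proteins, seeded."""
    cfg = GeneratorConfig(n_compounds=80, n_proteins=12, pair_density=0.4, seed=11)
    return make_benchmark(cfg)


@pytest.fixture(scope="session")
def small_curated(small_benchmark):
    b = small_benchmark
    pairs, report = curate(b.records, b.compounds, b.fingerprints,
                           CurationConfig(seed=11))
    return pairs, report


@pytest.fixture(scope="session")
def golden():
    """The 12-record hand-checkable curation fixture."""
    return golden_curation_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
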