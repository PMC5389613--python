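import pytest
from hypothesis import settings

from bulkpop import FrequencyTable, GeneratorConfig, LocusDef
from bulkpop.synth import generate_dataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def locus_di() -> LocusDef:
    """Dinucleotide SSR with ladder 100, 102, ..., 160."""
    return LocusDef("ssrA", "1.01", 2, 100, 160)


@pytest.fixture
def two_pop_table() -> FrequencyTable:
    return FrequencyTable(
        {
            "p1": {"ssrA": {100: 0.3, 104: 0.7}, "ssrB": {200: 1.0}},
            "p2": {"ssrA": {100: 0.6, 104: 0.4}, "ssrB": {200: 0.5, 203: 0.5}},
        }
    )


@pytest.fixture(scope="session")
def study_scale_dataset():
    """Synthetic stand-in with the surveyed data's shape: 194 population
    bulks of 15 plants scored at 28 SSR loci, three ancestral groups."""
    cfg = GeneratorConfig(k_true=3, n_populations=194, n_loci=28, seed=7)
    return generate_dataset(cfg, render_peaks=False)


@pytest.fixture(scope="session")
def small_k2_dataset():
    """Small two-cluster dataset for sampler recovery tests."""
    cfg = GeneratorConfig(
        k_true=2, n_populations=12, n_loci=12, drift_f=0.3, admix_alpha=0.1,
        n_individuals=10, seed=5,
    )
    return generate_dataset(cfg, render_peaks=False)
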