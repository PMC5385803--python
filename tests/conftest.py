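import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microsad import GutDesignSpec, OTUTable, TaxonomyMap, generate_gut_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def small_table() -> OTUTable:
    """3 samples x 4 OTUs with hand-checkable counts."""
    counts = [
        [5, 3, 2, 0],
        [1, 1, 1, 1],
        [0, 0, 0, 7],
    ]
    return OTUTable(counts, sample_ids=["s1", "s2", "s3"], otu_ids=["a", "b", "c", "d"])


@pytest.fixture
def small_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        {
            "a": "Firmicutes;Clostridiales",
            "b": "Firmicutes;Lactobacillales",
            "c": "Proteobacteria",
            "d": "Actinobacteria;Bifidobacteriales",
        }
    )


@pytest.fixture(scope="session")
def gut_dataset():
    """One default-design synthetic dataset, shared across tests."""
    return generate_gut_dataset(GutDesignSpec(seed=20140826))


def random_abundance_vectors(n, rng=None, max_species=40, max_count=60):
    """Random integer abundance vectors for property checks."""
    rng = rng or np.random.default_rng(0)
    out = []
    for _ in range(n):
        S = int(rng.integers(1, max_species + 1))
        out.append(rng.integers(1, max_count + 1, size=S))
    return out
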