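import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonalgp import (
    SimulationConfig,
    build_numerator_relationship,
    filter_markers,
    impute_gene_content,
    simulate_dataset,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_dataset():
    """One full study draw at reduced marker count, shared read-only."""
    cfg = SimulationConfig(n_markers=300)
    return simulate_dataset(cfg, 42)


@pytest.fixture(scope="session")
def A_clones(base_dataset):
    A = build_numerator_relationship(base_dataset.pedigree)
    return A.submatrix(base_dataset.genotypes.clone_ids)


@pytest.fixture(scope="session")
def imputed_genotypes(base_dataset, A_clones):
    filtered, _ = filter_markers(base_dataset.genotypes)
    return impute_gene_content(filtered, A_clones, variant="truncated")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two families, 16 clones, small ramet counts: cheap exact checks."""
    cfg = SimulationConfig(
        n_parents=4,
        n_families=2,
        n_progeny=16,
        progeny_per_family=(6, 10),
        n_markers=200,
        n_sites=3,
        ramets_per_clone=(3, 6),
        missing_rate=0.0,
    )
    return simulate_dataset(cfg, 7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
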