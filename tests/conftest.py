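import numpy as np
import pytest

from icarmap import (
    AdjacencyList,
    ModelSpec,
    SamplerConfig,
    SyntheticScenario,
    build_model,
    equal_weights,
    expected_counts,
    generate_dataset,
    reference_rates,
    run_mcmc,
)


@pytest.fixture(scope="session")
def chain3():
    """Path graph 1-2-3 (0-based)."""
    return AdjacencyList.from_pairs(3, [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def grid3_scenario():
    return SyntheticScenario(n_rows=3, n_cols=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """5x5 synthetic dataset used by several model-level tests."""
    return generate_dataset(SyntheticScenario(n_rows=5, n_cols=5, seed=42))


@pytest.fixture(scope="session")
def quick_config():
    """Short sampler run for smoke-level model tests."""
    return SamplerConfig(n_chains=2, burn_in=1500, keep=1000, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_dataset, quick_config):
    ds = small_dataset
    z = reference_rates(ds.table)
    E = expected_counts(ds.table, z)
    spec = ModelSpec(E=E, weights=equal_weights(ds.adjacency), X=ds.X)
    model = build_model(ds.table.area_totals, spec)
    return run_mcmc(model, quick_config)
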