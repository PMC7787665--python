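import numpy as np
import pandas as pd
import pytest

from subpop.synth import SynthConfig, simulate_counts, simulate_cell_sizes, simulate_flow_events


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def default_data(default_config):
    """Pinned default synthetic dataset (counts + truth)."""
    return simulate_counts(default_config)


@pytest.fixture(scope="session")
def default_sizes(default_config):
    return simulate_cell_sizes(default_config)


@pytest.fixture(scope="session")
def default_flow(default_config):
    return simulate_flow_events(default_config)


@pytest.fixture(scope="session")
def small_config():
    """Small, fast configuration for I/O-level tests."""
    return SynthConfig(seed=7, n_proteins_symbiont=40, n_proteins_host=12,
                       n_objects_per_fraction=200, n_objects_homogenate=400,
                       flow_events_per_sample=500, flow_n_samples=2)


@pytest.fixture(scope="session")
def small_data(small_config):
    return simulate_counts(small_config)
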