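import numpy as np
import pandas as pd
import pytest

from phylorao import phylo_io, synthetic_data


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def three_tip_tree():
    return phylo_io.read_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def two_clade_tree():
    """Deep two-clade tree: two tight clades separated by long stems."""
    left = ",".join(f"L{i}:0.1" for i in range(6))
    right = ",".join(f"R{i}:0.1" for i in range(6))
    return phylo_io.read_newick(f"(({left}):5.0,({right}):5.0):0;")


@pytest.fixture
def random_community(rng):
    counts = rng.integers(0, 20, size=(10, 15))
    counts[counts.sum(axis=1) == 0, 0] = 1
    return pd.DataFrame(
        counts,
        index=[f"p{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(15)],
    )


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small but complete synthetic dataset used across pipeline tests."""
    config = synthetic_data.ScenarioConfig(
        n_plots=12, n_plant_species=30, n_bird_species=15, seed=1234
    )
    return synthetic_data.simulate_dataset(config, n_posterior=4,
                                           jitter_cv=0.05)


def random_distance_matrix(rng, n, scale=1.0):
    """Random symmetric hollow non-negative matrix (not necessarily
    metric — fine for Rao/MPD/Mantel inputs)."""
    vals = rng.uniform(0, scale, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return vals
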