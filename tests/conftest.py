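import numpy as np
import pandas as pd
import pytest

from phylorates import (SimulationConfig, parse_newick, simulate_dataset,
                        simulate_tree)


@pytest.fixture
def small_tree():
    """Three-tip tree with a hand-computable covariance matrix."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule20():
    """A fixed 20-tip unit-height Yule chronogram."""
    return simulate_tree(20, seed=42)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small complete synthetic study: 5 effect + 5 null genes, 2 alignments."""
    cfg = SimulationConfig(seed=3, n_species=15, n_effect_genes=5,
                           n_null_genes=5, n_alignments=2,
                           n_null_records=30, n_alt_records=10)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_spd(n: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((n, n))
    return A @ A.T + n * np.eye(n)


@pytest.fixture
def phenotype_table():
    return pd.DataFrame({
        "species": ["meerkat_like", "ferret_like", "cat_like", "otter_like",
                    "bear_like", "walrus_like"],
        "body_mass_g": [730.0, 975.6, 4000.0, 27400.0, 200000.0, 4e6],
        "head_body_length_cm": [29.0, 45.0, 46.0, 120.0, 210.0, 320.0],
    })
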