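"""Shared fixtures: a small synthetic dataset for fast end-to-end tests.

The mini fixture is deliberately smaller than the standard benchmark
fixture (fewer genes, cells and spots, shorter training) so module and
pipeline tests stay quick; the full-size standard fixture is exercised by
the acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from spotdecon import RunConfig
from spotdecon.benchmark import generate_synthetic_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

MINI_KW = dict(
    K=3,
    genes_per_type=40,
    n_background_genes=30,
    n_cells=90,
    n_spots=49,
    grid=(7, 7),
    fold_change=8.0,
    seed=7,
)

FAST_CONFIG = dict(
    pretrain_epochs=15,
    finetune_epochs=30,
    max_epochs=300,
    seed=7,
)


@pytest.fixture(scope="session")
def mini_fixture():
    """(reference, srt, truth) triple at desk-test scale."""
    return generate_synthetic_fixture(**MINI_KW)


@pytest.fixture(scope="session")
def fast_config():
    return RunConfig(**FAST_CONFIG)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
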