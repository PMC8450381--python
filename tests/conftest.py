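"""Shared fixtures: skin model, chromophores, and MC training datasets.

Two dataset scales are used: a small 5x5 grid at 2e4 paths/band for unit
tests, and the 10x10 grid at 1e5 paths/band (the reduced study scale)
shared by the acceptance tests. Both are session-scoped so the Monte
Carlo cost is paid once.
"""
import numpy as np
import pytest

from veinviz.optics_data import (default_skin_stack, default_chromophores,
                                 DEFAULT_GRID, REGRESSION_GRID)
from veinviz.mc_skin import PhotonRunConfig, build_training_grid


@pytest.fixture(scope="session")
def stack():
    return default_skin_stack()


@pytest.fixture(scope="session")
def chroms():
    return default_chromophores()


@pytest.fixture(scope="session")
def pairs_small(stack):
    """5x5 training grid at reduced path count, for fast unit tests."""
    cfg = PhotonRunConfig(n_photons=20_000, seed=11)
    return build_training_grid(5, 5, cfg, stack)


@pytest.fixture(scope="session")
def pairs_study(stack):
    """10x10 grid at 1e5 paths/band: the reduced study-scale dataset."""
    cfg = PhotonRunConfig(n_photons=100_000, seed=1)
    return build_training_grid(10, 10, cfg, stack)


@pytest.fixture(scope="session")
def visualizer(pairs_study):
    from veinviz.pipeline import VeinVisualizer
    return VeinVisualizer(pairs_study)


@pytest.fixture(scope="session")
def visualizer_small(pairs_small):
    from veinviz.pipeline import VeinVisualizer
    return VeinVisualizer(pairs_small)
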