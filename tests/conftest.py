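"""Shared fixtures: small landscapes, meshes, and the one expensive
parameter-recovery MCMC run (session-scoped, reused by several tests)."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

from movesynd.hierarchy import MCMCConfig, run_mcmc
from movesynd.landscape import FOREST, OPEN, HabitatPolygonSet, build_mesh
from movesynd.synthetic import make_dataset, small_study_config


@pytest.fixture(scope="session")
def forest_square() -> HabitatPolygonSet:
    """1000 x 1000 m single forest square."""
    return HabitatPolygonSet([(box(0, 0, 1000, 1000), FOREST)], (0, 0, 1000, 1000))


@pytest.fixture(scope="session")
def bipartite_square() -> HabitatPolygonSet:
    """2000 x 2000 m square: forest left half, open right half."""
    return HabitatPolygonSet(
        [(box(0, 0, 1000, 2000), FOREST), (box(1000, 0, 2000, 2000), OPEN)],
        (0, 0, 2000, 2000),
    )


@pytest.fixture(scope="session")
def forest_mesh(forest_square):
    return build_mesh(forest_square, 5000.0)


@pytest.fixture(scope="session")
def bipartite_mesh(bipartite_square):
    return build_mesh(bipartite_square, 31250.0)  # 250 m pitch


@pytest.fixture(scope="session")
def tiny_mesh():
    """A 32-triangle (5 x 5 vertex) single-habitat mesh, 2 km across."""
    habitat = HabitatPolygonSet([(box(0, 0, 2000, 2000), FOREST)], (0, 0, 2000, 2000))
    mesh = build_mesh(habitat, 125000.0)  # 500 m pitch
    assert mesh.n_triangles <= 50
    return mesh


@pytest.fixture(scope="session")
def small_study():
    """The bundled desk-scale synthetic study (15 individuals, 20 slots)."""
    return make_dataset(small_study_config(), seed=3)


@pytest.fixture(scope="session")
def recovery_fit(small_study):
    """Hierarchical MCMC fit of the bundled study: 2 chains x (2k + 8k).

    The one long-running fixture; parameter-recovery, convergence and
    predictive tests all reuse it.
    """
    data = small_study.study_data()
    config = MCMCConfig(n_adapt=2000, n_iter=8000, n_chains=2, seed=11)
    chains = run_mcmc(data, config)
    return small_study, data, chains


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
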