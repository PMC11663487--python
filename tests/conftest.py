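"""Shared fixtures: small simulated datasets and cached trained models."""

import numpy as np
import pytest

from spagate import (GateConfig, SimConfig, TrainConfig, build_hybrid_graph,
                     preprocess, simulate, train)
from spagate.io_preprocess import ExpressionMatrix, SpatialCoords

#: quick fixture for unit tests: 10x10 grid, 2 domains, 100 genes
UNIT_SIM = SimConfig(grid_shape=(10, 10), n_domains=2, n_genes=100,
                     markers_per_domain=20, seed=11)


@pytest.fixture(scope="session")
def unit_data():
    expr, coords, truth = simulate(UNIT_SIM)
    pp = preprocess(expr)
    graph = build_hybrid_graph(pp, coords)
    return pp, coords, graph, truth


@pytest.fixture(scope="session")
def trained_unit(unit_data):
    """A short default-objective training run on the unit fixture."""
    pp, coords, graph, truth = unit_data
    gate_config = GateConfig(layer_dims=(pp.n_genes, 32, 16), seed=3)
    train_config = TrainConfig(epochs=60, seed=3)
    state, emb = train(pp, coords, graph, gate_config, train_config)
    return state, emb, gate_config, train_config


@pytest.fixture()
def toy_pair():
    """Five spots on a line with four genes; small enough to hand-check."""
    rng = np.random.default_rng(0)
    expr = ExpressionMatrix(rng.uniform(0.5, 2.0, size=(5, 4)),
                            [f"s{i}" for i in range(5)],
                            [f"g{j}" for j in range(4)])
    coords = SpatialCoords(np.column_stack([np.arange(5.0), np.zeros(5)]),
                           expr.spot_ids)
    return expr, coords
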