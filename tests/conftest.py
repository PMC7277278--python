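"""Shared fixtures: small road networks and a reusable synthetic scenario."""

import numpy as np
import pytest

import gravroute as gr


@pytest.fixture(scope="session")
def detour_network():
    """Origin s, destination t; a direct shortest path (via a), an
    admissible 20%-longer alternative (via u, v) and a locally suboptimal
    variant of it detouring u -> w -> v.  Weights are tie-free."""
    edges = [
        ("s", "a", 2.0),
        ("a", "t", 2.0),
        ("s", "u", 1.5),
        ("u", "v", 1.8),
        ("v", "t", 1.5),
        ("u", "w", 0.9),
        ("w", "v", 1.2),
    ]
    return gr.RoadNetwork(edges, {"s": "origin", "t": "destination"})


@pytest.fixture(scope="session")
def small_scenario():
    """Compact synthetic study system shared across fitting tests."""
    config = gr.ScenarioConfig(
        n_origins=6,
        n_destinations=30,
        n_vertices=90,
        n_stations=6,
        n_shifts=240,
        extent=(400.0, 300.0),  # compact region: plenty of long-distance trips
        seed=11,
    )
    return gr.generate_scenario(config)


def random_connected_graph(rng: np.random.Generator, n_max: int = 12):
    """Random connected weighted graph with tie-free float weights."""
    import networkx as nx

    while True:
        n = int(rng.integers(5, n_max + 1))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g) or g.number_of_edges() < n:
            continue
        edges = [
            (str(u), str(v), float(rng.uniform(1.0, 10.0))) for u, v in g.edges
        ]
        return gr.RoadNetwork(edges)
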