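"""Shared fixtures: synthetic tissues and hand-built networks."""

import numpy as np
import pytest

from epimech import inference, network, synth
from epimech.network import Cell, Junction, TissueNetwork


@pytest.fixture(scope="session")
def tissue_200():
    """Exact equilibrium Voronoi tissue, 200 cells, seed 1."""
    cfg = synth.SyntheticConfig(n_cells=200, seed=1)
    net, truth = synth.generate_equilibrium_network(cfg)
    return cfg, net, truth


@pytest.fixture(scope="session")
def inferred_200(tissue_200):
    cfg, net, truth = tissue_200
    restricted = network.restrict_threefold(net)
    inf = inference.infer_tensions(restricted)
    return restricted, inf


def triangular_lattice(nx=10, ny=10, a=30.0, origin=20.0):
    """Triangular lattice points; their Voronoi cells are regular hexagons."""
    pts = []
    for j in range(ny):
        for i in range(nx):
            x = origin + i * a + (a / 2 if j % 2 else 0.0)
            y = origin + j * a * np.sqrt(3) / 2
            pts.append((x, y))
    return np.array(pts)


def four_cell_network():
    """Four cells a, b, c, d around one vertical central junction.

    Cell a on the left, b on the right, d below (at the start vertex),
    c above (at the end vertex). Neighbour junction ids: 11 = T1 (b, d),
    12 = T2 (a, d), 13 = T3 (a, c), 14 = T4 (b, c); central junction 10
    has length 2.
    """
    V = {
        1: np.array([0.0, 0.0]),  # start vertex (d side)
        2: np.array([0.0, 2.0]),  # end vertex (c side)
        3: np.array([1.5, -1.5]),
        4: np.array([-1.5, -1.5]),
        5: np.array([-1.5, 3.5]),
        6: np.array([1.5, 3.5]),
    }

    def jun(jid, va, vb, cells):
        path = np.vstack([V[va], V[vb]])
        return Junction(
            id=jid,
            vertices=(va, vb),
            path=path,
            cells=cells,
            length=float(np.linalg.norm(path[1] - path[0])),
            angle=network.fold_angle(path[1] - path[0], (1.0, 0.0)),
            is_boundary=False,
        )

    junctions = {
        10: jun(10, 1, 2, (1, 2)),  # central, cells (a, b)
        11: jun(11, 1, 3, (2, 4)),  # T1 (b, d)
        12: jun(12, 1, 4, (1, 4)),  # T2 (a, d)
        13: jun(13, 2, 5, (1, 3)),  # T3 (a, c)
        14: jun(14, 2, 6, (2, 3)),  # T4 (b, c)
    }
    cells = {
        1: Cell(1, [10, 12, 13], [1, 2], np.array([-1.0, 1.0])),
        2: Cell(2, [10, 11, 14], [1, 2], np.array([1.0, 1.0])),
        3: Cell(3, [13, 14], [2], np.array([0.0, 3.0])),
        4: Cell(4, [11, 12], [1], np.array([0.0, -1.0])),
    }
    return TissueNetwork(vertices=V, junctions=junctions, cells=cells)


FOUR_CELL_TENSIONS = {10: 1.0, 11: 3.0, 12: 1.0, 13: 2.0, 14: 1.0}


@pytest.fixture
def hand_net():
    return four_cell_network()
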