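import numpy as np
import pytest
from shapely.geometry import box

from fooddesert.spatial import AreaGraph, adjacency_from_polygons


def grid_polygons(nrows: int, ncols: int) -> dict:
    return {
        f"G{r * ncols + c:03d}": box(c, r, c + 1, r + 1)
        for r in range(nrows)
        for c in range(ncols)
    }


@pytest.fixture(scope="session")
def grid3x3() -> AreaGraph:
    return adjacency_from_polygons(grid_polygons(3, 3))


@pytest.fixture(scope="session")
def grid4x4() -> AreaGraph:
    return adjacency_from_polygons(grid_polygons(4, 4))


@pytest.fixture(scope="session")
def grid5x5() -> AreaGraph:
    return adjacency_from_polygons(grid_polygons(5, 5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230627)


def random_graph(rng: np.random.Generator, n: int, p_edge: float = 0.3) -> AreaGraph:
    """Erdos-Renyi-style random contiguity graph on n areas."""
    ids = tuple(f"R{i:02d}" for i in range(n))
    nbrs = {a: set() for a in ids}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < p_edge:
                nbrs[ids[i]].add(ids[j])
                nbrs[ids[j]].add(ids[i])
    return AreaGraph(ids, {a: frozenset(s) for a, s in nbrs.items()})


def dense_laplacian(graph: AreaGraph) -> np.ndarray:
    """Independent D - A construction straight from the neighbor sets."""
    n = graph.n
    idx = {a: k for k, a in enumerate(graph.area_ids)}
    L = np.zeros((n, n))
    for a in graph.area_ids:
        i = idx[a]
        L[i, i] = len(graph.neighbors[a])
        for b in graph.neighbors[a]:
            L[i, idx[b]] = -1.0
    return L
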