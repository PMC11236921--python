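"""Areal contiguity graphs and the intrinsic CAR (ICAR) quadratic form.

The spatially structured random effect u in a BYM count model is smoothed
over a neighborhood graph of the areal units (census tracts).  This module
builds that graph — queen contiguity from polygons, or an explicit edge
list — and provides the ICAR energy Sum_{i~j} (u_i - u_j)^2 on which both
the sampler and the synthetic-data generator rely.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import shape
from shapely.strtree import STRtree

__all__ = [
    "AreaGraph",
    "adjacency_from_polygons",
    "adjacency_from_edge_list",
    "read_geojson_polygons",
    "icar_energy",
    "icar_logpdf_unnorm",
]


@dataclass(frozen=True)
class AreaGraph:
    """Symmetric contiguity structure over areal units.

    Vectors indexed by area are always aligned to ``area_ids``, which is
    kept in sorted order so that every table produced downstream can be
    joined on the id column without positional ambiguity.

    Attributes
    ----------
    area_ids : tuple
        Unique area identifiers, sorted.
    neighbors : dict
        Mapping id -> frozenset of neighboring ids (no self loops).
    connected : bool
        Whether the graph is a single connected component.  ICAR on a
        disconnected graph needs a sum-to-zero constraint per component,
        which the sampler and simulator honour via ``components``.
    """

    area_ids: tuple
    neighbors: dict
    connected: bool = field(init=False)
    # derived index-space views, populated in __post_init__
    n: int = field(init=False)
    degrees: np.ndarray = field(init=False)
    edges: np.ndarray = field(init=False)  # (m, 2) int index pairs, i < j
    components: tuple = field(init=False)  # tuples of int indices
    islands: tuple = field(init=False)  # ids with degree 0

    def __post_init__(self):
        ids = tuple(self.area_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate area ids")
        index = {a: k for k, a in enumerate(ids)}
        g = nx.Graph()
        g.add_nodes_from(ids)
        for a, nbrs in self.neighbors.items():
            for b in nbrs:
                if a == b:
                    raise ValueError(f"self-loop at area {a!r}")
                if a not in index or b not in index:
                    raise ValueError(f"edge references unknown area {a!r}-{b!r}")
                g.add_edge(a, b)
        # symmetrize the stored adjacency
        sym = {a: frozenset(g.neighbors(a)) for a in ids}
        object.__setattr__(self, "neighbors", sym)
        object.__setattr__(self, "area_ids", ids)
        object.__setattr__(self, "n", len(ids))
        deg = np.array([len(sym[a]) for a in ids], dtype=float)
        object.__setattr__(self, "degrees", deg)
        edges = np.array(
            sorted((min(index[a], index[b]), max(index[a], index[b])) for a, b in g.edges()),
            dtype=int,
        ).reshape(-1, 2)
        object.__setattr__(self, "edges", edges)
        comps = tuple(
            tuple(sorted(index[a] for a in comp)) for comp in nx.connected_components(g)
        )
        comps = tuple(sorted(comps))
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "connected", len(comps) == 1)
        islands = tuple(a for a in ids if len(sym[a]) == 0)
        object.__setattr__(self, "islands", islands)
        if islands:
            warnings.warn(
                f"{len(islands)} island area(s) with no neighbors: {islands[:5]}; "
                "their structured effect is fixed at 0",
                stacklevel=3,
            )

    @property
    def index(self) -> dict:
        return {a: k for k, a in enumerate(self.area_ids)}

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - A in area_ids order."""
        L = np.diag(self.degrees.copy())
        for i, j in self.edges:
            L[i, j] -= 1.0
            L[j, i] -= 1.0
        return L

    def icar_rank(self) -> int:
        """Rank of the ICAR precision: sum of (|component| - 1), islands excluded."""
        return sum(len(c) - 1 for c in self.components if len(c) > 1)

    def coloring(self) -> list:
        """Greedy proper coloring as a list of index arrays (for chromatic updates)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        colors = nx.greedy_color(g, strategy="largest_first")
        ncol = 1 + max(colors.values()) if colors else 1
        return [
            np.array(sorted(k for k, c in colors.items() if c == col), dtype=int)
            for col in range(ncol)
        ]

    def to_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\n")
            for i, j in self.edges:
                fh.write(f"{self.area_ids[i]}\t{self.area_ids[j]}\n")

    def summary(self) -> dict:
        return {
            "n_areas": self.n,
            "n_edges": int(len(self.edges)),
            "n_components": len(self.components),
            "connected": self.connected,
            "n_islands": len(self.islands),
        }


def adjacency_from_polygons(geometries) -> AreaGraph:
    """Queen-contiguity graph from polygons: any shared boundary point links two areas.

    Parameters
    ----------
    geometries : dict or iterable of (id, shapely geometry)
        Area polygons keyed by unique id.

    Raises
    ------
    ValueError
        On empty input, duplicate ids, or an invalid geometry (named).
    """
    if isinstance(geometries, dict):
        items = list(geometries.items())
    else:
        items = list(geometries)
    if not items:
        raise ValueError("empty polygon collection")
    ids = [a for a, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area ids in polygon collection")
    geoms = []
    for a, g in items:
        if g is None or g.is_empty or not g.is_valid:
            raise ValueError(f"invalid geometry for area {a!r}")
        geoms.append(g)
    tree = STRtree(geoms)
    neighbors = {a: set() for a in ids}
    for k, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j != k:
                neighbors[ids[k]].add(ids[j])
                neighbors[ids[j]].add(ids[k])
    graph = AreaGraph(tuple(sorted(ids)), {a: frozenset(s) for a, s in neighbors.items()})
    if not graph.connected:
        warnings.warn(
            f"contiguity graph is disconnected ({len(graph.components)} components)",
            stacklevel=2,
        )
    return graph


def adjacency_from_edge_list(path, area_ids=None) -> AreaGraph:
    """Read a two-column (id_a, id_b) whitespace/tab-delimited edge list.

    ``area_ids`` may supply the full node set (so isolated areas are kept);
    otherwise the node set is the union of the edge endpoints.
    """
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0] in {"id_a", "#"}:
                continue
            if len(parts) < 2:
                raise ValueError(f"malformed edge-list line: {line!r}")
            edges.append((parts[0], parts[1]))
    if area_ids is None:
        area_ids = sorted({a for e in edges for a in e})
    neighbors = {a: set() for a in area_ids}
    for a, b in edges:
        if a not in neighbors or b not in neighbors:
            raise ValueError(f"edge {a!r}-{b!r} references an area not in area_ids")
        neighbors[a].add(b)
        neighbors[b].add(a)
    return AreaGraph(tuple(sorted(area_ids)), {a: frozenset(s) for a, s in neighbors.items()})


def read_geojson_polygons(path) -> dict:
    """Load a GeoJSON FeatureCollection into {area_id: shapely geometry}.

    The area id is taken from the feature property ``area_id`` (fallback:
    ``id``, then the feature-level ``id`` member).
    """
    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        aid = props.get("area_id", props.get("id", feat.get("id")))
        if aid is None:
            raise ValueError("feature without an area_id/id property")
        out[aid] = shape(feat["geometry"])
    return out


def icar_energy(u, graph: AreaGraph) -> float:
    """Pairwise-difference quadratic form Sum_{i~j} (u_i - u_j)^2 over neighbor pairs.

    Over unordered neighbor pairs this equals the Laplacian quadratic form
    u'(D-A)u; the ICAR log-density (up to a constant) is -(tau_u/2) * energy.
    Island areas contribute nothing (they have no neighbor pairs).
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (graph.n,):
        raise ValueError(f"u has length {u.shape}, expected ({graph.n},)")
    if len(graph.edges) == 0:
        return 0.0
    d = u[graph.edges[:, 0]] - u[graph.edges[:, 1]]
    return float(d @ d)


def icar_logpdf_unnorm(u, graph: AreaGraph, tau_u: float) -> float:
    """Unnormalized ICAR log-density -(tau_u/2) * icar_energy(u).

    Invariant under u -> u + c per connected component (improper prior);
    samplers must impose a sum-to-zero constraint to identify the level.
    """
    if tau_u <= 0:
        raise ValueError("tau_u must be positive")
    return -0.5 * tau_u * icar_energy(u, graph)
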