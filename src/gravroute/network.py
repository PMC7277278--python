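"""Road-network representation and admissible-path enumeration.

The road network is an undirected graph whose vertices are junctions,
origin/destination anchors and survey stations, and whose edge weights are
travel times in minutes.  Agents travelling between an origin ``i`` and a
destination ``j`` are assumed to choose among a small set of *admissible*
paths: single-via paths (a shortest path constrained through one
intermediate vertex) whose total length is at most ``gamma`` times the
shortest travel time and which contain no *local detour* -- every subpath
shorter than ``delta`` times the path length must itself be a shortest path
between its endpoints.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RoadNetwork",
    "Path",
    "AdmissiblePathSet",
    "shortest_distance",
    "enumerate_admissible_paths",
]

#: relative tolerance used when comparing path lengths to shortest distances
LENGTH_RTOL = 1e-9

VALID_ROLES = {"junction", "origin", "destination", "station"}


@dataclass(frozen=True)
class Path:
    """A simple path through the road network.

    Attributes
    ----------
    vertices
        Ordered vertex sequence; consecutive vertices are adjacent and no
        vertex repeats.
    length
        Total travel time in minutes (sum of edge weights).
    """

    vertices: tuple
    length: float

    def __len__(self) -> int:
        return len(self.vertices)

    def edges(self) -> list[tuple]:
        return list(zip(self.vertices[:-1], self.vertices[1:]))

    def contains_station(self, station: Hashable) -> bool:
        """True if ``station`` lies strictly between the path endpoints.

        Surveys happen en route, so endpoint vertices never count as
        station passages.
        """
        return station in self.vertices[1:-1]


class RoadNetwork:
    """Weighted road graph with vertex roles.

    Parameters
    ----------
    edges
        Iterable of ``(u, v, travel_time_minutes)``; weights must be
        strictly positive and finite.
    roles
        Mapping vertex -> role in ``{"junction", "origin", "destination",
        "station"}``.  Vertices appearing in edges but not in ``roles``
        default to junctions.
    """

    def __init__(
        self,
        edges: Iterable[tuple[Hashable, Hashable, float]],
        roles: Mapping[Hashable, str] | None = None,
    ) -> None:
        g = nx.Graph()
        for u, v, w in edges:
            w = float(w)
            if not (w > 0 and math.isfinite(w)):
                raise ValueError(f"edge ({u!r}, {v!r}) has invalid weight {w!r}")
            g.add_edge(u, v, weight=w)
        self.graph = g
        self.roles: dict = {}
        roles = dict(roles or {})
        for v in g.nodes:
            self.roles[v] = roles.pop(v, "junction")
        for v, role in roles.items():  # role-only vertices must exist
            raise KeyError(f"role given for unknown vertex {v!r}")
        bad = {v: r for v, r in self.roles.items() if r not in VALID_ROLES}
        if bad:
            raise ValueError(f"invalid roles: {bad}")
        self._spt_cache: dict = {}

    # -- convenience accessors ------------------------------------------
    def vertices_with_role(self, role: str) -> list:
        return sorted(v for v, r in self.roles.items() if r == role)

    @property
    def origins(self) -> list:
        return self.vertices_with_role("origin")

    @property
    def destinations(self) -> list:
        return self.vertices_with_role("destination")

    @property
    def stations(self) -> list:
        return self.vertices_with_role("station")

    def edge_weight(self, u, v) -> float:
        return self.graph.edges[u, v]["weight"]

    def path_length(self, vertices: Sequence) -> float:
        return sum(self.edge_weight(u, v) for u, v in zip(vertices[:-1], vertices[1:]))

    # -- shortest paths -------------------------------------------------
    def shortest_path_tree(self, source) -> tuple[dict, dict]:
        """Dijkstra from ``source`` with deterministic tie-breaking.

        Among equally short paths the lexicographically smallest vertex
        sequence wins, so enumeration results are reproducible.

        Returns ``(dist, pred)`` where ``pred[v]`` is the predecessor of
        ``v`` on the canonical shortest path from ``source``.
        """
        if source in self._spt_cache:
            return self._spt_cache[source]
        if source not in self.graph:
            raise KeyError(f"unknown vertex {source!r}")
        g = self.graph
        dist: dict = {}
        pred: dict = {}
        # heap entries carry the full path tuple so that ties resolve
        # lexicographically; paths are short so this stays cheap
        heap: list = [(0.0, (source,))]
        while heap:
            d, path = heapq.heappop(heap)
            v = path[-1]
            if v in dist:
                continue
            dist[v] = d
            pred[v] = path[-2] if len(path) > 1 else None
            for u, attrs in g[v].items():
                if u not in dist:
                    heapq.heappush(heap, (d + attrs["weight"], path + (u,)))
        self._spt_cache[source] = (dist, pred)
        return dist, pred

    def shortest_path(self, source, target) -> Path | None:
        """Canonical shortest path, or ``None`` if unreachable."""
        dist, pred = self.shortest_path_tree(source)
        if target not in dist:
            return None
        seq = [target]
        while pred[seq[-1]] is not None:
            seq.append(pred[seq[-1]])
        seq.reverse()
        return Path(tuple(seq), dist[target])

    def clear_cache(self) -> None:
        self._spt_cache.clear()

    # -- I/O ------------------------------------------------------------
    @classmethod
    def from_frames(cls, edges: pd.DataFrame, roles: pd.DataFrame | None = None) -> "RoadNetwork":
        """Build from edge-list and vertex-role tables.

        ``edges`` needs columns ``from, to, travel_time``; ``roles`` needs
        ``vertex, role``.
        """
        edge_iter = (
            (r["from"], r["to"], r["travel_time"]) for _, r in edges.iterrows()
        )
        role_map = None
        if roles is not None:
            role_map = dict(zip(roles["vertex"], roles["role"]))
        return cls(edge_iter, role_map)


@dataclass
class AdmissiblePathSet:
    """Admissible paths for one origin--destination pair.

    Invariants: the shortest path is always a member, every member has
    length at most ``gamma`` times the shortest length, and members are
    unique vertex sequences.  ``unreachable`` marks disconnected pairs
    (empty path list).
    """

    origin: Hashable
    destination: Hashable
    paths: list[Path] = field(default_factory=list)
    gamma: float = 1.4
    delta: float = 0.2
    unreachable: bool = False

    @property
    def shortest_length(self) -> float:
        if not self.paths:
            return math.inf
        return min(p.length for p in self.paths)

    def lengths(self) -> np.ndarray:
        return np.array([p.length for p in self.paths], dtype=float)

    def station_incidence(self, stations: Sequence) -> np.ndarray:
        """Boolean matrix ``(n_paths, n_stations)``: path passes station."""
        return np.array(
            [[p.contains_station(k) for k in stations] for p in self.paths],
            dtype=bool,
        ).reshape(len(self.paths), len(stations))


def shortest_distance(
    network: RoadNetwork,
    origins: Sequence,
    destinations: Sequence,
) -> pd.DataFrame:
    """Shortest travel times (minutes) between vertex sets.

    Unreachable pairs get ``inf`` (downstream mean flow is then zero).
    """
    out = np.full((len(origins), len(destinations)), np.inf)
    for a, i in enumerate(origins):
        dist, _ = network.shortest_path_tree(i)
        for b, j in enumerate(destinations):
            out[a, b] = dist.get(j, math.inf)
    return pd.DataFrame(out, index=list(origins), columns=list(destinations))


def _is_locally_optimal(
    network: RoadNetwork, vertices: tuple, length: float, delta: float
) -> bool:
    """No subpath of along-path length <= delta*length may beat the
    network shortest distance between its endpoints."""
    n = len(vertices)
    # prefix sums of along-path distance
    cum = [0.0]
    for u, v in zip(vertices[:-1], vertices[1:]):
        cum.append(cum[-1] + network.edge_weight(u, v))
    limit = delta * length
    tol = 1.0 + LENGTH_RTOL
    for a in range(n - 1):
        dist_a = None
        for b in range(a + 1, n):
            seg = cum[b] - cum[a]
            if seg > limit * tol:
                break
            if dist_a is None:
                dist_a, _ = network.shortest_path_tree(vertices[a])
            if seg > dist_a[vertices[b]] * tol:
                return False
    return True


def enumerate_admissible_paths(
    network: RoadNetwork,
    origin: Hashable,
    destination: Hashable,
    gamma: float = 1.4,
    delta: float = 0.2,
) -> AdmissiblePathSet:
    """Enumerate admissible single-via paths between an OD pair.

    Candidates are concatenations of the canonical shortest paths
    ``origin -> v`` and ``v -> destination`` over every via vertex ``v``
    (plus the plain shortest path), restricted to simple paths.  Candidates
    longer than ``gamma`` times the shortest travel time or containing a
    local detour at scale ``delta`` are discarded.
    """
    if not (gamma >= 1):
        raise ValueError("gamma must be >= 1")
    if not (0 <= delta <= 1):
        raise ValueError("delta must lie in [0, 1]")
    if origin == destination:
        raise ValueError("origin and destination must differ")

    dist_i, pred_i = network.shortest_path_tree(origin)
    if destination not in dist_i:
        return AdmissiblePathSet(origin, destination, [], gamma, delta, unreachable=True)
    dist_j, pred_j = network.shortest_path_tree(destination)
    l_star = dist_i[destination]
    bound = gamma * l_star * (1.0 + LENGTH_RTOL)

    def walk(pred, v) -> list:
        seq = [v]
        while pred[seq[-1]] is not None:
            seq.append(pred[seq[-1]])
        return seq

    candidates: dict[tuple, float] = {}
    sp = network.shortest_path(origin, destination)
    candidates[sp.vertices] = sp.length
    for v in network.graph.nodes:
        if v == origin or v == destination:
            continue
        if v not in dist_i or v not in dist_j:
            continue
        total = dist_i[v] + dist_j[v]
        if total > bound:
            continue
        first = walk(pred_i, v)[::-1]  # origin .. v
        second = walk(pred_j, v)  # v .. destination
        seq = tuple(first + second[1:])
        if len(set(seq)) != len(seq):  # not simple
            continue
        candidates.setdefault(seq, total)

    paths = []
    for seq in sorted(candidates):
        length = candidates[seq]
        if length > bound:
            continue
        if _is_locally_optimal(network, seq, length, delta):
            paths.append(Path(seq, length))
    paths.sort(key=lambda p: (p.length, p.vertices))
    return AdmissiblePathSet(origin, destination, paths, gamma, delta)
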