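"""Synthetic road networks, covariates and simulated survey datasets.

The generator emulates the structure of a large-scale vector-traffic
survey system: a planar road network (travel times in minutes) with
origins clustered on one side and destination lakes spread over the rest,
survey stations on high-betweenness corridor vertices, origin/destination
covariates on the scales the gravity parameters expect (populations in
millions, lake areas in km^2, near-lake populations in thousands), and
roadside survey shifts during daytime hours.

Surveys can be simulated two ways.  ``mode="agents"`` samples every agent
individually through the observation hierarchy (trip, realised route,
passage time, compliance) -- the event-level ground truth used to validate
the marginal passage probabilities.  ``mode="cells"`` draws each
(shift, OD) count directly from the closed-form negative-binomial
observation law; this matches the fitted model exactly and is used for
gravity parameter-recovery studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .compliance import ComplianceData, ComplianceParams
from .fitting import CountDataset
from .gravity import GravityParams, MINUTES_SCALE, mean_flow, nb_shape
from .network import AdmissiblePathSet, RoadNetwork, enumerate_admissible_paths, shortest_distance
from .routechoice import RouteChoiceParams, choice_probabilities
from .temporal import PERIOD, SurveyShift, TemporalParams

__all__ = ["ScenarioConfig", "Scenario", "generate_scenario", "simulate_surveys"]


@dataclass
class ScenarioConfig:
    """Configuration of a synthetic study system.

    The default sizes (20 origins, 100 destinations, 300 vertices, 12
    stations, 500 shifts) run the full pipeline in a few minutes on one
    CPU while keeping every submodel identifiable.
    """

    n_origins: int = 20
    n_destinations: int = 100
    n_vertices: int = 300
    n_stations: int = 12
    n_shifts: int = 500
    shifts_per_day: int = 2
    #: daytime survey windows (hours); drawn uniformly per shift
    shift_windows: tuple[tuple[float, float], ...] = (
        (8.0, 14.0),
        (9.0, 17.0),
        (10.0, 16.0),
        (11.0, 16.0),
        (12.0, 18.0),
    )
    #: rectangle the road network lives on, in minutes of travel
    extent: tuple[float, float] = (900.0, 600.0)
    #: fraction of non-tree candidate edges kept (road-density knob)
    extra_edge_frac: float = 0.55
    #: road windiness: edge time = Euclidean time * U(1, 1+windiness)
    windiness: float = 0.3
    gamma: float = 1.4
    delta: float = 0.2
    gravity: GravityParams = field(default_factory=GravityParams)
    route_choice: RouteChoiceParams = field(default_factory=RouteChoiceParams)
    temporal: TemporalParams = field(default_factory=TemporalParams)
    compliance: ComplianceParams = field(
        default_factory=lambda: ComplianceParams(0.80, 0.93, 0.744)
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("n_origins", "n_destinations", "n_vertices", "n_stations", "n_shifts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.n_origins + self.n_destinations + self.n_stations > self.n_vertices:
            raise ValueError("not enough vertices for the requested roles")


@dataclass
class Scenario:
    """A generated study system with its true parameters."""

    config: ScenarioConfig
    network: RoadNetwork
    origin_cov: pd.DataFrame
    dest_cov: pd.DataFrame
    distances: pd.DataFrame  # minutes, origins x destinations
    path_sets: dict[tuple, AdmissiblePathSet]
    mu: pd.DataFrame  # true mean daily OD flows

    @property
    def od_pairs(self) -> list[tuple]:
        return [(i, j) for i in self.distances.index for j in self.distances.columns]

    def mu_dict(self) -> dict[tuple, float]:
        return {
            (i, j): float(self.mu.loc[i, j])
            for i in self.mu.index
            for j in self.mu.columns
        }


def _build_network(config: ScenarioConfig, rng: np.random.Generator) -> tuple[RoadNetwork, dict]:
    """Planar-ish connected road graph: Delaunay triangulation thinned to
    a spanning tree plus a random subset of extra edges."""
    from scipy.spatial import Delaunay

    n = config.n_vertices
    w, h = config.extent
    pts = rng.uniform((0, 0), (w, h), size=(n, 2))
    tri = Delaunay(pts)
    cand = set()
    for simplex in tri.simplices:
        for a in range(3):
            u, v = int(simplex[a]), int(simplex[(a + 1) % 3])
            cand.add((min(u, v), max(u, v)))
    g = nx.Graph()
    for u, v in cand:
        dist = float(np.linalg.norm(pts[u] - pts[v]))
        g.add_edge(u, v, weight=dist * rng.uniform(1.0, 1.0 + config.windiness))
    mst = nx.minimum_spanning_tree(g, weight="weight")
    extra = [e for e in g.edges if e not in mst.edges]
    keep = rng.random(len(extra)) < config.extra_edge_frac
    road = nx.Graph()
    road.add_weighted_edges_from((u, v, g.edges[u, v]["weight"]) for u, v in mst.edges)
    for (u, v), k in zip(extra, keep):
        if k:
            road.add_edge(u, v, weight=g.edges[u, v]["weight"])

    # roles: origins in the eastern strip, destinations elsewhere,
    # stations on high-betweenness corridor vertices
    labels = {v: f"v{v:04d}" for v in road.nodes}
    x = pts[:, 0]
    east = np.argsort(-x)
    origins = [int(v) for v in east[: config.n_origins]]
    remaining = [int(v) for v in range(n) if v not in set(origins)]
    west = sorted(remaining, key=lambda v: x[v])
    dest_pool = west[: max(config.n_destinations * 2, config.n_destinations)]
    destinations = sorted(
        rng.choice(dest_pool, size=config.n_destinations, replace=False).tolist()
    )
    betw = nx.betweenness_centrality(road, weight="weight", normalized=True)
    taken = set(origins) | set(destinations)
    station_rank = sorted(
        (v for v in road.nodes if v not in taken), key=lambda v: -betw[v]
    )
    stations = station_rank[: config.n_stations]

    roles = {labels[v]: "junction" for v in road.nodes}
    for v in origins:
        roles[labels[v]] = "origin"
    for v in destinations:
        roles[labels[v]] = "destination"
    for v in stations:
        roles[labels[v]] = "station"
    edges = (
        (labels[u], labels[v], road.edges[u, v]["weight"]) for u, v in road.edges
    )
    return RoadNetwork(edges, roles), {labels[v]: pts[v] for v in road.nodes}


def _draw_covariates(
    config: ScenarioConfig, network: RoadNetwork, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    origins = network.origins
    dests = network.destinations
    origin_cov = pd.DataFrame(
        {
            "pop": rng.lognormal(math.log(3.0), 1.0, len(origins)),
            "CA": rng.random(len(origins)) < 0.5,
        },
        index=origins,
    ).astype({"CA": int})
    dest_cov = pd.DataFrame(
        {
            "A": rng.lognormal(math.log(100.0), 1.5, len(dests)),
            "camp": rng.random(len(dests)) < 0.4,
            "fac": rng.random(len(dests)) < 0.5,
            "mar": rng.random(len(dests)) < 0.15,
            "lpop": rng.lognormal(math.log(2.0), 1.5, len(dests)),
        },
        index=dests,
    ).astype({"camp": int, "fac": int, "mar": int})
    return origin_cov, dest_cov


def generate_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Generate a synthetic study system.

    Deterministic given ``config.seed``.  Disconnected OD pairs (possible
    in principle, not with the default generator) are flagged unreachable
    and carry zero flow.
    """
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed)
    for attempt in range(5):
        network, _ = _build_network(config, rng)
        dist = shortest_distance(network, network.origins, network.destinations)
        if np.isfinite(dist.to_numpy()).all():
            break
    else:
        raise RuntimeError("could not generate a connected scenario")
    origin_cov, dest_cov = _draw_covariates(config, network, rng)

    g = config.gravity
    from .gravity import DestinationCovariates, OriginCovariates

    mu = pd.DataFrame(0.0, index=network.origins, columns=network.destinations)
    for i in network.origins:
        oc = OriginCovariates(origin_cov.loc[i, "pop"], origin_cov.loc[i, "CA"])
        d_row = dist.loc[i].to_numpy()
        dc = DestinationCovariates(
            A=dest_cov["A"].to_numpy(),
            camp=dest_cov["camp"].to_numpy(),
            fac=dest_cov["fac"].to_numpy(),
            mar=dest_cov["mar"].to_numpy(),
            lpop=dest_cov["lpop"].to_numpy(),
        )
        mu.loc[i] = mean_flow(g, oc, dc, d_row)

    path_sets = {}
    for i in network.origins:
        for j in network.destinations:
            path_sets[(i, j)] = enumerate_admissible_paths(
                network, i, j, config.gamma, config.delta
            )
    return Scenario(config, network, origin_cov, dest_cov, dist, path_sets, mu)


def _make_shifts(config: ScenarioConfig, stations: list, rng: np.random.Generator) -> list[SurveyShift]:
    shifts = []
    for s in range(config.n_shifts):
        day = s // config.shifts_per_day
        station = stations[int(rng.integers(len(stations)))]
        start, end = config.shift_windows[int(rng.integers(len(config.shift_windows)))]
        shifts.append(SurveyShift(f"shift{s:05d}", station, start, end, date=day))
    return shifts


def _sample_vonmises_hours(
    temporal: TemporalParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    if temporal.kappa <= 1e-12:
        return rng.uniform(0.0, PERIOD, size)
    ang = stats.vonmises.rvs(temporal.kappa, size=size, random_state=rng)
    return (ang * PERIOD / (2.0 * math.pi) + temporal.theta) % PERIOD


def simulate_surveys(
    scenario: Scenario,
    mode: Literal["agents", "cells"] = "agents",
    seed: int | None = None,
    n_compliance_passes: int = 2000,
) -> tuple[CountDataset, ComplianceData, list[tuple[float, str]]]:
    """Simulate roadside survey data from a scenario.

    Returns the count dataset, pooled compliance counts and the survey
    time dataset (observation time, shift id).  See the module docstring
    for the two modes.  ``seed`` defaults to ``config.seed + 1``.
    """
    config = scenario.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    stations = scenario.network.stations
    shifts = _make_shifts(config, stations, rng)
    od_pairs = scenario.od_pairs
    mu_vec = np.array([scenario.mu.loc[i, j] for i, j in od_pairs])
    g = config.gravity
    rc = config.route_choice
    temporal = config.temporal
    xi = config.compliance

    records: list[dict] = []
    obs_times: list[tuple[float, str]] = []

    if mode == "cells":
        from .routechoice import station_probability_matrix
        from .temporal import window_probability

        rho = station_probability_matrix(
            [scenario.path_sets[od] for od in od_pairs], stations, rc
        )
        st_index = {k: a for a, k in enumerate(stations)}
        for shift in shifts:
            tau = window_probability(temporal, shift)
            means = mu_vec * rho[:, st_index[shift.station]] * tau * xi.xi
            if g.p < 1:
                counts = rng.negative_binomial(np.maximum(nb_shape(means, g.p), 1e-300), g.p)
            else:
                counts = rng.poisson(means)
            counts = np.where(means > 0, counts, 0)
            for idx in np.nonzero(counts)[0]:
                c = int(counts[idx])
                records.append(
                    {
                        "shift_id": shift.shift_id,
                        "origin": od_pairs[idx][0],
                        "destination": od_pairs[idx][1],
                        "count": c,
                    }
                )
                # passage times, conditioned on the shift window
                need = c
                while need > 0:
                    t = _sample_vonmises_hours(temporal, max(need * 4, 16), rng)
                    ok = t[[shift.contains(v) for v in t]][:need]
                    for v in ok:
                        obs_times.append((float(v), shift.shift_id))
                    need -= len(ok)
    elif mode == "agents":
        n_days = max(s.date for s in shifts) + 1
        shifts_by_day: dict[int, list[SurveyShift]] = {}
        for s in shifts:
            shifts_by_day.setdefault(s.date, []).append(s)
        # pre-draw choice probabilities per OD
        probs_cache = {}
        for od in od_pairs:
            ps = scenario.path_sets[od]
            if ps.paths:
                probs_cache[od] = (ps, choice_probabilities(ps, rc.lam))
        if g.p < 1:
            n_day_od = rng.negative_binomial(
                np.maximum(nb_shape(mu_vec, g.p), 1e-300), g.p, size=(n_days, len(od_pairs))
            )
        else:
            n_day_od = rng.poisson(mu_vec, size=(n_days, len(od_pairs)))
        n_day_od = np.where(mu_vec > 0, n_day_od, 0)
        counter: dict[tuple[str, tuple], int] = {}
        for day in range(n_days):
            day_shifts = shifts_by_day.get(day, [])
            if not day_shifts:
                continue
            active = np.nonzero(n_day_od[day])[0]
            for idx in active:
                od = od_pairs[idx]
                n_agents = int(n_day_od[day][idx])
                ps, probs = probs_cache.get(od, (None, None))
                adm = rng.random(n_agents) >= rc.eta_c
                times = _sample_vonmises_hours(temporal, n_agents, rng)
                if ps is not None:
                    path_idx = rng.choice(len(probs), size=n_agents, p=probs)
                for a in range(n_agents):
                    if adm[a] and ps is not None:
                        path = ps.paths[path_idx[a]]
                        passes = {k for k in stations if path.contains_station(k)}
                    else:
                        passes = {
                            k for k, u in zip(stations, rng.random(len(stations))) if u < rc.eta_o
                        }
                    if not passes:
                        continue
                    for shift in day_shifts:
                        if shift.station in passes and shift.contains(times[a]):
                            if rng.random() < xi.xi_p and rng.random() < xi.xi_c:
                                key = (shift.shift_id, od)
                                counter[key] = counter.get(key, 0) + 1
                                obs_times.append((float(times[a]), shift.shift_id))
        for (shift_id, od), c in counter.items():
            records.append(
                {"shift_id": shift_id, "origin": od[0], "destination": od[1], "count": c}
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rec = pd.DataFrame(records, columns=["shift_id", "origin", "destination", "count"])
    data = CountDataset(shifts, od_pairs, rec)

    # pooled compliance tallies from an independent passing stream
    stopped = int(rng.binomial(n_compliance_passes, xi.xi_p))
    complete = int(rng.binomial(stopped, xi.xi_c)) if stopped else 0
    compliance = ComplianceData(
        n_stopped=stopped,
        n_bypassed=n_compliance_passes - stopped,
        n_highrisk_stopped=stopped,
        n_highrisk_complete=complete,
    )
    return data, compliance, obs_times
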