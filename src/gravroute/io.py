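"""Dataset readers and writers.

All datasets are UTF-8 comma-separated files with headers; times of day
are decimal hours, travel times minutes, counts integers.  Five datasets
feed the model fit: survey counts, compliance tallies, survey times,
origin/destination covariates, and the road network (edge list plus
vertex roles).  Reading enforces cross-referential integrity -- every
count record must point at an existing shift and OD pair and every
observation time must fall inside its shift's window -- and fails hard
with the file, line and field of the first violation.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass
from pathlib import Path as FilePath

import numpy as np
import pandas as pd
import yaml

from .compliance import ComplianceData
from .fitting import CountDataset
from .network import RoadNetwork
from .temporal import SurveyShift

__all__ = [
    "DataError",
    "RunConfig",
    "read_network",
    "read_covariates",
    "read_shifts",
    "read_counts",
    "read_survey_times",
    "read_compliance",
    "read_datasets",
    "DatasetBundle",
    "write_scenario",
    "write_fit_report",
]


class DataError(ValueError):
    """Input-data violation, reported with file, line and field."""

    def __init__(self, path, line: int | None, field: str, message: str):
        self.path, self.line, self.field = str(path), line, field
        loc = f"{path}" + (f", line {line}" if line is not None else "")
        super().__init__(f"{loc}, field '{field}': {message}")


def _require_columns(df: pd.DataFrame, path, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(path, 1, ",".join(missing), "missing required column(s)")


def read_network(edges_path, roles_path) -> RoadNetwork:
    edges = pd.read_csv(edges_path)
    _require_columns(edges, edges_path, ["from", "to", "travel_time"])
    for idx, w in edges["travel_time"].items():
        if not (w > 0 and np.isfinite(w)):
            raise DataError(edges_path, idx + 2, "travel_time", f"invalid weight {w!r}")
    roles = pd.read_csv(roles_path)
    _require_columns(roles, roles_path, ["vertex", "role"])
    try:
        return RoadNetwork.from_frames(edges, roles)
    except (KeyError, ValueError) as exc:
        raise DataError(roles_path, None, "vertex/role", str(exc)) from exc


def read_covariates(origins_path, destinations_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    oc = pd.read_csv(origins_path)
    _require_columns(oc, origins_path, ["id", "pop", "CA"])
    dc = pd.read_csv(destinations_path)
    _require_columns(dc, destinations_path, ["id", "A", "camp", "fac", "mar", "lpop"])
    for path, df, cols in (
        (origins_path, oc, ["pop"]),
        (destinations_path, dc, ["A", "lpop"]),
    ):
        for col in cols:
            bad = df.index[df[col] < 0]
            if len(bad):
                raise DataError(path, int(bad[0]) + 2, col, "negative covariate")
    for col in ("CA",):
        if not oc[col].isin([0, 1]).all():
            raise DataError(origins_path, None, col, "indicator must be 0/1")
    for col in ("camp", "fac", "mar"):
        if not dc[col].isin([0, 1]).all():
            raise DataError(destinations_path, None, col, "indicator must be 0/1")
    return oc.set_index("id"), dc.set_index("id")


def read_shifts(path) -> list[SurveyShift]:
    df = pd.read_csv(path)
    _require_columns(df, path, ["shift_id", "station", "start", "end", "date"])
    if df["shift_id"].duplicated().any():
        line = int(df.index[df["shift_id"].duplicated()][0]) + 2
        raise DataError(path, line, "shift_id", "duplicate shift id")
    shifts = []
    for idx, r in df.iterrows():
        try:
            shifts.append(
                SurveyShift(
                    str(r["shift_id"]), r["station"], float(r["start"]),
                    float(r["end"]), int(r["date"]),
                )
            )
        except ValueError as exc:
            raise DataError(path, idx + 2, "start/end", str(exc)) from exc
    return shifts


def read_counts(path, shifts, od_pairs) -> CountDataset:
    df = pd.read_csv(path)
    _require_columns(df, path, ["shift_id", "origin", "destination", "count"])
    shift_ids = {s.shift_id for s in shifts}
    od = set(od_pairs)
    for idx, r in df.iterrows():
        if str(r["shift_id"]) not in shift_ids:
            raise DataError(path, idx + 2, "shift_id", f"unknown shift {r['shift_id']!r}")
        if (r["origin"], r["destination"]) not in od:
            raise DataError(
                path, idx + 2, "origin/destination",
                f"unknown OD pair ({r['origin']!r}, {r['destination']!r})",
            )
        c = r["count"]
        if c != int(c) or c < 0:
            raise DataError(path, idx + 2, "count", f"invalid count {c!r}")
    df["shift_id"] = df["shift_id"].astype(str)
    return CountDataset(list(shifts), list(od_pairs), df)


def read_survey_times(path, shifts) -> list[tuple[float, str]]:
    df = pd.read_csv(path)
    _require_columns(df, path, ["observation_id", "shift_id", "time"])
    by_id = {s.shift_id: s for s in shifts}
    out = []
    for idx, r in df.iterrows():
        sid = str(r["shift_id"])
        if sid not in by_id:
            raise DataError(path, idx + 2, "shift_id", f"unknown shift {sid!r}")
        t = float(r["time"])
        if not by_id[sid].contains(t):
            raise DataError(
                path, idx + 2, "time",
                f"observation time {t} outside shift window "
                f"[{by_id[sid].start}, {by_id[sid].end}]",
            )
        out.append((t, sid))
    return out


def read_compliance(path) -> ComplianceData:
    """Read per-shift compliance tallies and pool them.

    Shifts without bypass counting leave ``bypassed`` empty and then
    contribute only to the data-quality rate.
    """
    df = pd.read_csv(path)
    _require_columns(
        df, path, ["shift_id", "stopped", "bypassed", "highrisk_stopped", "highrisk_complete"]
    )
    total = ComplianceData(0, 0, 0, 0)
    for idx, r in df.iterrows():
        has_bypass = pd.notna(r["bypassed"])
        try:
            row = ComplianceData(
                int(r["stopped"]) if has_bypass else 0,
                int(r["bypassed"]) if has_bypass else 0,
                int(r["highrisk_stopped"]),
                int(r["highrisk_complete"]),
            )
        except ValueError as exc:
            raise DataError(path, idx + 2, "counts", str(exc)) from exc
        total = total + row
    return total


@dataclass
class RunConfig:
    """Paths and settings for a model-fitting run (YAML-serialisable)."""

    edges: str
    vertices: str
    origins: str
    destinations: str
    shifts: str
    counts: str
    survey_times: str
    compliance: str
    output_dir: str = "output"
    gamma: float = 1.4
    delta: float = 0.2
    free_parameters: tuple[str, ...] = ("c", "p", "alpha_d")
    n_restarts: int = 10
    seed: int = 0
    effort_weighting: str = "tau"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "free_parameters" in raw:
            raw["free_parameters"] = tuple(raw["free_parameters"])
        cfg = cls(**raw)
        base = FilePath(path).parent
        for name in (
            "edges", "vertices", "origins", "destinations",
            "shifts", "counts", "survey_times", "compliance",
        ):
            p = base / getattr(cfg, name)
            if not p.exists():
                raise DataError(path, None, name, f"referenced file {p} does not exist")
            setattr(cfg, name, str(p))
        return cfg

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class DatasetBundle:
    network: RoadNetwork
    origin_cov: pd.DataFrame
    dest_cov: pd.DataFrame
    shifts: list[SurveyShift]
    counts: CountDataset
    survey_times: list[tuple[float, str]]
    compliance: ComplianceData


def read_datasets(config: RunConfig) -> DatasetBundle:
    """Read and cross-validate all five datasets."""
    network = read_network(config.edges, config.vertices)
    origin_cov, dest_cov = read_covariates(config.origins, config.destinations)
    unknown_o = set(origin_cov.index) - set(network.origins)
    if unknown_o:
        raise DataError(config.origins, None, "id", f"origins not in network: {sorted(unknown_o)[:5]}")
    unknown_d = set(dest_cov.index) - set(network.destinations)
    if unknown_d:
        raise DataError(
            config.destinations, None, "id", f"destinations not in network: {sorted(unknown_d)[:5]}"
        )
    shifts = read_shifts(config.shifts)
    stations = set(network.stations)
    for s in shifts:
        if s.station not in stations:
            raise DataError(config.shifts, None, "station", f"unknown station {s.station!r}")
    od_pairs = [(i, j) for i in origin_cov.index for j in dest_cov.index]
    counts = read_counts(config.counts, shifts, od_pairs)
    survey_times = read_survey_times(config.survey_times, shifts)
    compliance = read_compliance(config.compliance)
    return DatasetBundle(network, origin_cov, dest_cov, shifts, counts, survey_times, compliance)


# ---------------------------------------------------------------------------
# writers


def write_scenario(scenario, data, compliance, survey_times, out_dir) -> dict[str, str]:
    """Write a simulated scenario in the CSV dialects read_datasets expects."""
    out = FilePath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = scenario.network
    paths = {}

    edges = pd.DataFrame(
        [
            {"from": u, "to": v, "travel_time": net.graph.edges[u, v]["weight"]}
            for u, v in sorted(net.graph.edges)
        ]
    )
    paths["edges"] = str(out / "edges.csv")
    edges.to_csv(paths["edges"], index=False)

    roles = pd.DataFrame(
        [{"vertex": v, "role": r} for v, r in sorted(net.roles.items())]
    )
    paths["vertices"] = str(out / "vertices.csv")
    roles.to_csv(paths["vertices"], index=False)

    paths["origins"] = str(out / "origins.csv")
    scenario.origin_cov.rename_axis("id").reset_index().to_csv(paths["origins"], index=False)
    paths["destinations"] = str(out / "destinations.csv")
    scenario.dest_cov.rename_axis("id").reset_index().to_csv(paths["destinations"], index=False)

    shifts = pd.DataFrame(
        [
            {"shift_id": s.shift_id, "station": s.station, "start": s.start,
             "end": s.end, "date": s.date}
            for s in data.shifts
        ]
    )
    paths["shifts"] = str(out / "shifts.csv")
    shifts.to_csv(paths["shifts"], index=False)

    paths["counts"] = str(out / "counts.csv")
    data.records.to_csv(paths["counts"], index=False)

    times = pd.DataFrame(
        [
            {"observation_id": f"obs{i:06d}", "shift_id": sid, "time": t}
            for i, (t, sid) in enumerate(survey_times)
        ],
        columns=["observation_id", "shift_id", "time"],
    )
    paths["survey_times"] = str(out / "survey_times.csv")
    times.to_csv(paths["survey_times"], index=False)

    comp = pd.DataFrame(
        [
            {
                "shift_id": "pooled",
                "stopped": compliance.n_stopped,
                "bypassed": compliance.n_bypassed,
                "highrisk_stopped": compliance.n_highrisk_stopped,
                "highrisk_complete": compliance.n_highrisk_complete,
            }
        ]
    )
    paths["compliance"] = str(out / "compliance.csv")
    comp.to_csv(paths["compliance"], index=False)
    return paths


def write_fit_report(path, rows: list[dict]) -> None:
    """Parameter report CSV: parameter, estimate, ci_low, ci_high."""
    pd.DataFrame(rows, columns=["parameter", "estimate", "ci_low", "ci_high"]).to_csv(
        path, index=False
    )
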