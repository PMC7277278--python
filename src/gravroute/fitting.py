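"""Hierarchical observation law, composite likelihood and staged fitting.

An agent is recorded in a survey shift if it travels (gravity model),
routes via the survey station (route choice), passes during the shift
window (temporal pattern), and complies (compliance model).  The observed
count for origin ``i``, destination ``j``, station ``k`` and shift ``t``
is modelled as negative binomial with mean

    mu_ij * rho_ijk * tau_t * xi

and the shared mean-to-variance ratio ``p``.

The composite log-likelihood is the sum of NB log-probabilities over every
(shift, OD) cell -- including the implicit zeros -- under a working
independence assumption across cells.  Cells sharing the same (mean, p)
are grouped so the all-zero bulk costs one closed-form evaluation per
group instead of one per cell.

Fitting is staged in the order inverse to the observation hierarchy:
compliance, temporal pattern, route choice, then gravity; the gravity fit
refuses to run without the upstream parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .ci import ProfileCI, profile_ci
from .compliance import ComplianceParams
from .gravity import (
    DestinationCovariates,
    GravityParams,
    OriginCovariates,
    mean_flow,
    nb_count_law,
)
from .network import AdmissiblePathSet
from .routechoice import ETA_C_MAX, RouteChoiceParams, station_probability_matrix
from .temporal import SurveyShift, TemporalFit, TemporalParams, window_probability

__all__ = [
    "CountDataset",
    "FittedModel",
    "shift_count_law",
    "nb_logpmf",
    "composite_log_likelihood",
    "monitoring_effort",
    "fit_route_choice",
    "RouteChoiceFit",
    "GravityFitProblem",
    "fit_gravity",
    "GravityFit",
    "aic_select",
]

#: relative quantization used to group cells with equal predicted means
GROUP_RTOL = 1e-12


# ---------------------------------------------------------------------------
# data container


@dataclass
class CountDataset:
    """Sparse survey counts: explicit nonzero records, implicit zeros.

    ``records`` has columns ``shift_id, origin, destination, count``; every
    (shift, OD) combination absent from it is an observed zero.
    ``od_pairs`` fixes the full set of OD pairs the likelihood ranges over.
    """

    shifts: list[SurveyShift]
    od_pairs: list[tuple]
    records: pd.DataFrame

    def __post_init__(self):
        required = {"shift_id", "origin", "destination", "count"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        counts = self.records["count"].to_numpy()
        if len(counts) and not np.array_equal(counts, counts.astype(int)):
            raise ValueError("counts must be integers")
        if len(counts) and (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        shift_ids = {s.shift_id for s in self.shifts}
        unknown = set(self.records["shift_id"]) - shift_ids
        if unknown:
            raise ValueError(f"records reference unknown shifts {sorted(unknown)[:5]}")
        od = set(self.od_pairs)
        for _, r in self.records.iterrows():
            if (r["origin"], r["destination"]) not in od:
                raise ValueError(
                    f"record references unknown OD pair ({r['origin']!r}, {r['destination']!r})"
                )

    @property
    def n_cells(self) -> int:
        return len(self.shifts) * len(self.od_pairs)

    def total_count(self) -> int:
        return int(self.records["count"].sum())


# ---------------------------------------------------------------------------
# count law and composite likelihood


def shift_count_law(mu: float, rho: float, tau: float, xi: float, p: float):
    """Distribution of the surveyed count in one (shift, OD) cell."""
    for name, v in (("rho", rho), ("tau", tau), ("xi", xi)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    return nb_count_law(mu * rho * tau * xi, p)


def nb_logpmf(n, mean, p):
    """Vectorized log-pmf of NB(mean, mean/variance ratio p).

    ``p = 1`` is the Poisson limit; zero means give a point mass at zero.
    """
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if p == 1.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = special.xlogy(n, mean) - mean - special.gammaln(n + 1.0)
        out = np.where((mean == 0) & (n == 0), 0.0, out)
        out = np.where((mean == 0) & (n > 0), -np.inf, out)
        return out
    r = mean * p / (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            special.gammaln(n + r)
            - special.gammaln(r)
            - special.gammaln(n + 1.0)
            + r * math.log(p)
            + n * math.log1p(-p)
        )
    out = np.where((mean == 0) & (n == 0), 0.0, out)
    out = np.where((mean == 0) & (n > 0), -np.inf, out)
    return out


def _nb_logpmf_zero(mean, p):
    """log P(N = 0) for NB(mean, ratio p): r log p, or -mean for Poisson."""
    if p == 1.0:
        return -np.asarray(mean, dtype=float)
    return np.asarray(mean, dtype=float) * (p / (1.0 - p)) * math.log(p)


def composite_log_likelihood(
    data: CountDataset,
    cell_means: Callable[[SurveyShift], np.ndarray] | Mapping[str, np.ndarray],
    p: float,
    *,
    grouped: bool = True,
) -> float:
    """Composite log-likelihood of a count dataset.

    ``cell_means`` maps each shift (or shift id) to the vector of predicted
    means over ``data.od_pairs``.  With ``grouped=True`` shifts whose mean
    vectors coincide (same station, same window probability) share one
    zero-bulk evaluation; the naive double loop is kept as an oracle.
    """
    od_index = {od: r for r, od in enumerate(data.od_pairs)}
    n_od = len(data.od_pairs)

    def means_for(shift: SurveyShift) -> np.ndarray:
        if callable(cell_means):
            m = cell_means(shift)
        else:
            m = cell_means[shift.shift_id]
        m = np.asarray(m, dtype=float)
        if m.shape != (n_od,):
            raise ValueError("cell_means must return one mean per OD pair")
        return m

    rec_by_shift: dict[str, list[tuple[int, int]]] = {}
    for _, r in data.records.iterrows():
        rec_by_shift.setdefault(r["shift_id"], []).append(
            (od_index[(r["origin"], r["destination"])], int(r["count"]))
        )

    if not grouped:
        total = 0.0
        for shift in data.shifts:
            means = means_for(shift)
            counts = np.zeros(n_od)
            for idx, c in rec_by_shift.get(shift.shift_id, []):
                counts[idx] += c
            total += float(nb_logpmf(counts, means, p).sum())
        return total

    # group shifts by quantized mean vector
    groups: dict[bytes, list[SurveyShift]] = {}
    group_means: dict[bytes, np.ndarray] = {}
    for shift in data.shifts:
        means = means_for(shift)
        scale = np.abs(means).max()
        if scale == 0:
            key = b"zero"
            q = means
        else:
            q = np.round(means / (scale * GROUP_RTOL)) * (scale * GROUP_RTOL)
            key = q.tobytes()
        groups.setdefault(key, []).append(shift)
        group_means.setdefault(key, q)

    total = 0.0
    for key, members in groups.items():
        means = group_means[key]
        lp0 = _nb_logpmf_zero(means, p)
        total += len(members) * float(lp0.sum())
        for shift in members:
            for idx, c in rec_by_shift.get(shift.shift_id, []):
                if c:
                    total += float(nb_logpmf(c, means[idx], p) - lp0[idx])
    return total


# ---------------------------------------------------------------------------
# route-choice conditional fit


def monitoring_effort(
    shifts: Sequence[SurveyShift],
    temporal: TemporalParams,
    weighting: str = "tau",
) -> dict:
    """Per-station monitoring effort w_k.

    ``"tau"`` weights each shift by the probability mass of the daily
    traffic pattern inside its window (the default); ``"duration"`` weights
    by shift length in hours.
    """
    effort: dict = {}
    for s in shifts:
        if weighting == "tau":
            w = window_probability(temporal, s)
        elif weighting == "duration":
            w = s.duration
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        effort[s.station] = effort.get(s.station, 0.0) + w
    return effort


@dataclass
class RouteChoiceFit:
    params: RouteChoiceParams
    log_likelihood: float
    cis: dict[str, ProfileCI] = field(default_factory=dict)
    identifiable: bool = True
    n_obs: int = 0

    @property
    def n_free(self) -> int:
        return 3


class _RouteChoiceNLL:
    """Conditional NLL of observed stations given OD and monitoring effort.

    An agent with OD pair (i, j) surveyed anywhere contributes
    ``-log( rho_ijk * w_k / sum_k' rho_ijk' * w_k' )`` for the station k
    where it was recorded, with the sum over all monitored stations.
    """

    def __init__(
        self,
        od_counts: np.ndarray,  # (n_od, n_stations) observed agents
        path_sets: Sequence[AdmissiblePathSet],
        stations: Sequence,
        effort: np.ndarray,  # (n_stations,)
    ):
        self.stations = list(stations)
        self.effort = np.asarray(effort, dtype=float)
        keep = od_counts.sum(axis=1) > 0
        self.counts = od_counts[keep]
        self.row_tot = self.counts.sum(axis=1)
        self.od_data = []
        for ps in np.asarray(path_sets, dtype=object)[keep]:
            lengths = ps.lengths()
            incid = ps.station_incidence(self.stations).astype(float)
            self.od_data.append((lengths / lengths.min(), incid))

    def __call__(self, x) -> float:
        lam, eta_c, eta_o = float(x[0]), float(x[1]), float(x[2])
        if lam < 0 or not 0 <= eta_c <= ETA_C_MAX or not 0 <= eta_o <= 1:
            return 1e15
        total = 0.0
        noise = eta_c * eta_o
        for (rel_len, incid), counts, row_tot in zip(
            self.od_data, self.counts, self.row_tot
        ):
            w = rel_len**-lam
            probs = w / w.sum()
            rho = (1.0 - eta_c) * probs @ incid + noise
            weighted = rho * self.effort
            denom = weighted.sum()
            if denom <= 0:
                return 1e15
            with np.errstate(divide="ignore"):
                lp = np.log(weighted) - math.log(denom)
            contrib = counts @ np.where(counts > 0, lp, 0.0)
            if not np.isfinite(contrib):
                return 1e15
            total -= contrib
        return total


def fit_route_choice(
    data: CountDataset,
    path_sets: Mapping[tuple, AdmissiblePathSet],
    effort: Mapping[Hashable, float],
    *,
    compute_ci: bool = True,
    level: float = 0.95,
    lam_max: float = 50.0,
    n_restarts: int = 4,
    seed: int = 0,
) -> RouteChoiceFit:
    """Fit (lambda, eta_c, eta_o) by conditional maximum likelihood.

    ``effort`` is the per-station monitoring effort (see
    :func:`monitoring_effort`); only stations with positive effort enter
    the conditioning.  ``eta_c`` is estimated on [0, 0.05]; when the bound
    is active the interval is truncated there.
    """
    stations = sorted(k for k, w in effort.items() if w > 0)
    if len(stations) < 2:
        raise ValueError("need at least two monitored stations")
    st_index = {k: a for a, k in enumerate(stations)}
    ps_list = [path_sets[od] for od in data.od_pairs]
    od_index = {od: r for r, od in enumerate(data.od_pairs)}
    counts = np.zeros((len(data.od_pairs), len(stations)))
    shift_station = {s.shift_id: s.station for s in data.shifts}
    for _, r in data.records.iterrows():
        k = shift_station[r["shift_id"]]
        if k in st_index:
            counts[od_index[(r["origin"], r["destination"])], st_index[k]] += r["count"]
    n_obs = int(counts.sum())
    if n_obs == 0:
        raise ValueError("no surveyed agents with known OD")

    # lambda is unidentifiable if every observed OD has a single admissible
    # path (the choice model then never discriminates)
    multi = [
        len(ps_list[r].paths) > 1 for r in range(len(ps_list)) if counts[r].sum() > 0
    ]
    identifiable = any(multi)
    if not identifiable:
        warnings.warn(
            "every observed OD pair has a single admissible route; "
            "lambda is not identifiable"
        )

    nll = _RouteChoiceNLL(counts, ps_list, stations, [effort[k] for k in stations])
    bounds = [(0.0, lam_max), (0.0, ETA_C_MAX), (0.0, 1.0)]
    rng = np.random.default_rng(seed)
    starts = [[5.0, 0.02, 0.1]]
    for _ in range(n_restarts - 1):
        starts.append(
            [rng.uniform(0.5, 15.0), rng.uniform(0, ETA_C_MAX), rng.uniform(0.01, 0.5)]
        )
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    lam_hat, eta_c_hat, eta_o_hat = best.x
    params = RouteChoiceParams(float(lam_hat), float(eta_c_hat), float(eta_o_hat))
    fit = RouteChoiceFit(params, -float(best.fun), identifiable=identifiable, n_obs=n_obs)

    if compute_ci:
        names = ["lam", "eta_c", "eta_o"]
        mle = np.array(best.x, dtype=float)
        warm = {i: mle.copy() for i in range(3)}

        def make_profile(i):
            others = [j for j in range(3) if j != i]

            def prof(value):
                x0 = warm[i].copy()
                x0[i] = value

                def obj(y):
                    x = x0.copy()
                    x[others] = y
                    return nll(x)

                res = optimize.minimize(
                    obj, x0[others], method="L-BFGS-B", bounds=[bounds[j] for j in others]
                )
                warm[i][others] = res.x
                warm[i][i] = value
                return float(res.fun)

            return prof

        for i, name in enumerate(names):
            fit.cis[name] = profile_ci(
                make_profile(i), float(mle[i]), float(best.fun), bounds[i][0], bounds[i][1], level
            )
    return fit


# ---------------------------------------------------------------------------
# gravity composite fit


_POSITIVE_PARAMS = {
    "c",
    "alpha_d",
    "pop0",
    "A0",
    "lpop0",
    "alpha_pop",
    "alpha_A",
    "alpha_lpop",
    "beta_CA",
    "beta_camp",
    "beta_fac",
    "beta_mar",
    "beta_lpop",
}


@dataclass
class GravityFit:
    params: GravityParams
    log_likelihood: float
    free: list[str]
    cis: dict[str, ProfileCI] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.log_likelihood


class GravityFitProblem:
    """Composite-likelihood fitting problem for the gravity stage.

    Bundles the count data with the (already fitted) route-choice,
    temporal and compliance submodels plus covariates and travel times,
    and exposes the negative composite log-likelihood as a function of the
    free gravity parameters.

    Parameters
    ----------
    data
        Survey counts.
    origin_cov, dest_cov
        Covariate tables indexed by origin / destination id with columns
        ``pop, CA`` and ``A, camp, fac, mar, lpop``.
    distances
        Travel-time matrix in minutes (origins x destinations).
    path_sets
        Admissible paths per OD pair.
    route_choice, temporal, compliance
        Upstream submodels; all three are required (staged-fit order).
    """

    def __init__(
        self,
        data: CountDataset,
        origin_cov: pd.DataFrame,
        dest_cov: pd.DataFrame,
        distances: pd.DataFrame,
        path_sets: Mapping[tuple, AdmissiblePathSet],
        route_choice: RouteChoiceParams,
        temporal: TemporalParams,
        compliance: ComplianceParams,
    ):
        for name, v in (
            ("route_choice", route_choice),
            ("temporal", temporal),
            ("compliance", compliance),
        ):
            if v is None:
                raise ValueError(
                    f"gravity fitting requires the fitted {name} submodel "
                    "(staged order: compliance -> temporal -> route choice -> gravity)"
                )
        self.data = data
        self.od_pairs = list(data.od_pairs)
        n_od = len(self.od_pairs)
        self.xi = compliance.xi
        self.p_fallback = None

        origins = [od[0] for od in self.od_pairs]
        dests = [od[1] for od in self.od_pairs]
        self.origin_cov = OriginCovariates(
            pop=origin_cov.loc[origins, "pop"].to_numpy(dtype=float),
            CA=origin_cov.loc[origins, "CA"].to_numpy(dtype=float),
        )
        self.dest_cov = DestinationCovariates(
            A=dest_cov.loc[dests, "A"].to_numpy(dtype=float),
            camp=dest_cov.loc[dests, "camp"].to_numpy(dtype=float),
            fac=dest_cov.loc[dests, "fac"].to_numpy(dtype=float),
            mar=dest_cov.loc[dests, "mar"].to_numpy(dtype=float),
            lpop=dest_cov.loc[dests, "lpop"].to_numpy(dtype=float),
        )
        self.d_minutes = np.array(
            [distances.loc[i, j] for i, j in self.od_pairs], dtype=float
        )

        stations = sorted({s.station for s in data.shifts})
        self.stations = stations
        rho = station_probability_matrix(
            [path_sets[od] for od in self.od_pairs], stations, route_choice
        )  # (n_od, n_stations)
        st_index = {k: a for a, k in enumerate(stations)}

        # group shifts by (station, quantized tau)
        group_key_of_shift: dict[str, int] = {}
        keys: dict[tuple, int] = {}
        self.group_rho: list[np.ndarray] = []
        self.group_tau: list[float] = []
        self.group_size: list[int] = []
        for s in data.shifts:
            tau = window_probability(temporal, s)
            key = (s.station, round(tau / GROUP_RTOL))
            if key not in keys:
                keys[key] = len(keys)
                self.group_rho.append(rho[:, st_index[s.station]])
                self.group_tau.append(tau)
                self.group_size.append(0)
            g = keys[key]
            self.group_size[g] += 1
            group_key_of_shift[s.shift_id] = g
        self.group_size = np.asarray(self.group_size)

        od_index = {od: r for r, od in enumerate(self.od_pairs)}
        self.rec_group = []
        self.rec_od = []
        self.rec_count = []
        for _, r in data.records.iterrows():
            if r["count"] == 0:
                continue
            self.rec_group.append(group_key_of_shift[r["shift_id"]])
            self.rec_od.append(od_index[(r["origin"], r["destination"])])
            self.rec_count.append(int(r["count"]))
        self.rec_group = np.asarray(self.rec_group, dtype=int)
        self.rec_od = np.asarray(self.rec_od, dtype=int)
        self.rec_count = np.asarray(self.rec_count, dtype=float)
        # per-group thinning factors rho * tau * xi as a matrix
        self.thin = (
            np.asarray(self.group_rho) * np.asarray(self.group_tau)[:, None] * self.xi
        )  # (n_groups, n_od)
        self.rec_thin = self.thin[self.rec_group, self.rec_od]

    def mu(self, params: GravityParams) -> np.ndarray:
        return np.asarray(
            mean_flow(params, self.origin_cov, self.dest_cov, self.d_minutes)
        )

    def log_likelihood(self, params: GravityParams) -> float:
        mu = self.mu(params)
        if not np.all(np.isfinite(mu)):
            return -np.inf
        means = self.thin * mu[None, :]  # (n_groups, n_od)
        p = params.p
        lp0 = _nb_logpmf_zero(means, p)
        total = float(self.group_size @ lp0.sum(axis=1))
        if len(self.rec_count):
            rec_means = self.rec_thin * mu[self.rec_od]
            total += float(
                (
                    nb_logpmf(self.rec_count, rec_means, p)
                    - _nb_logpmf_zero(rec_means, p)
                ).sum()
            )
        return total


def _pack(params: GravityParams, free: Sequence[str]) -> np.ndarray:
    out = []
    for name in free:
        v = getattr(params, name)
        if name == "p":
            out.append(math.log(v / (1.0 - v)) if v < 1 else 30.0)
        elif name in _POSITIVE_PARAMS:
            out.append(math.log(v))
        else:
            out.append(v)
    return np.asarray(out)


def _unpack(x: np.ndarray, base: GravityParams, free: Sequence[str]) -> GravityParams:
    kw = {}
    for name, v in zip(free, x):
        if name == "p":
            kw[name] = 1.0 / (1.0 + math.exp(-min(v, 30.0)))
        elif name in _POSITIVE_PARAMS:
            kw[name] = math.exp(min(v, 500.0))
        else:
            kw[name] = v
    return base.updated(**kw)


def fit_gravity(
    problem: GravityFitProblem,
    start: GravityParams | None = None,
    free: Sequence[str] = ("c", "p", "alpha_d"),
    *,
    n_restarts: int = 10,
    seed: int = 0,
    compute_ci: bool = True,
    level: float = 0.95,
) -> GravityFit:
    """Maximise the composite likelihood over the free gravity parameters.

    Positive parameters are optimised on the log scale and ``p`` on the
    logit scale; ``n_restarts`` multi-starts (perturbed around ``start``)
    guard against local optima.  Profile-likelihood intervals are computed
    for every free parameter.
    """
    free = list(free)
    base = start if start is not None else GravityParams()
    x0 = _pack(base, free)

    # large finite penalty instead of inf keeps numeric gradients usable
    _PENALTY = 1e15

    def nll(x):
        try:
            params = _unpack(x, base, free)
        except (ValueError, OverflowError):
            return _PENALTY
        with np.errstate(over="ignore"):
            ll = problem.log_likelihood(params)
        return -ll if np.isfinite(ll) else _PENALTY

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(x0 + rng.normal(scale=0.5, size=len(free)))
    best = None
    n_ok = 0
    for s in starts:
        if nll(s) >= _PENALTY:
            continue
        res = optimize.minimize(nll, s, method="L-BFGS-B")
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("gravity fit failed to converge from any start")
    params_hat = _unpack(best.x, base, free)
    fit = GravityFit(params_hat, -float(best.fun), free, converged=n_ok > 0)

    if compute_ci:
        # profile on the optimiser (log / logit) scale, where the
        # likelihood is closer to quadratic and bounds are additive
        mle = np.array(best.x, dtype=float)
        warm = {i: mle.copy() for i in range(len(free))}

        def to_natural(name, v):
            if name == "p":
                return 1.0 / (1.0 + math.exp(-min(v, 30.0)))
            if name in _POSITIVE_PARAMS:
                return math.exp(v)
            return v

        for i, name in enumerate(free):
            others = [j for j in range(len(free)) if j != i]

            def prof(v, i=i, others=others):
                x0p = warm[i].copy()
                x0p[i] = v
                if not others:
                    return float(nll(x0p))

                def obj(y):
                    x = x0p.copy()
                    x[others] = y
                    return nll(x)

                # refit from the warm start and from the MLE; a failed warm
                # start (penalty plateau) must not poison later evaluations
                results = [optimize.minimize(obj, x0p[others], method="L-BFGS-B")]
                if not np.array_equal(x0p[others], mle[others]):
                    results.append(optimize.minimize(obj, mle[others], method="L-BFGS-B"))
                res = min(results, key=lambda r: r.fun)
                if res.fun < _PENALTY:
                    warm[i][others] = res.x
                    warm[i][i] = v
                return float(res.fun)

            half_span = 20.7 if name == "p" else 13.8
            ci_t = profile_ci(
                prof, float(mle[i]), float(best.fun),
                mle[i] - half_span, mle[i] + half_span, level,
            )
            fit.cis[name] = ProfileCI(
                to_natural(name, ci_t.lower),
                to_natural(name, ci_t.upper),
                level,
                ci_t.lower_open,
                ci_t.upper_open,
            )
    return fit


# ---------------------------------------------------------------------------
# null model (for Nagelkerke's pseudo-R^2)


@dataclass
class NullModelFit:
    """Non-informative reference model: one constant cell mean (scaled by
    shift duration under a uniform daily pattern) and one dispersion."""

    mean_per_day: float
    p: float
    log_likelihood: float

    @property
    def n_free(self) -> int:
        return 2


def fit_null_model(data: CountDataset) -> NullModelFit:
    """Fit the null observation model by maximum likelihood.

    The null assumes a uniform daily traffic pattern, a route-choice model
    carrying no route information (every station equally likely) and a
    constant mean OD flow: the expected count of every (shift, OD) cell is
    ``m0 * duration / 24`` with one shared ``m0`` (which absorbs the
    constant passage and compliance probabilities) and one shared ``p``.
    """
    n_od = len(data.od_pairs)
    durations: dict[str, float] = {s.shift_id: s.duration for s in data.shifts}
    dur_counts: dict[float, int] = {}
    for s in data.shifts:
        dur_counts[s.duration] = dur_counts.get(s.duration, 0) + 1
    durs = np.array(list(dur_counts))
    n_shifts_by_dur = np.array([dur_counts[d] for d in durs], dtype=float)
    rec_dur = np.array(
        [durations[sid] for sid in data.records["shift_id"]], dtype=float
    )
    rec_count = data.records["count"].to_numpy(dtype=float)

    def nll(x):
        log_m0, logit_p = x
        m0 = math.exp(min(log_m0, 200.0))
        p = 1.0 / (1.0 + math.exp(-min(logit_p, 30.0)))
        means = m0 * durs / 24.0
        lp0 = _nb_logpmf_zero(means, p)
        total = float((n_shifts_by_dur * lp0).sum()) * n_od
        if len(rec_count):
            rm = m0 * rec_dur / 24.0
            total += float(
                (nb_logpmf(rec_count, rm, p) - _nb_logpmf_zero(rm, p)).sum()
            )
        return -total if np.isfinite(total) else 1e15

    mean_count = max(rec_count.sum() / max(data.n_cells, 1), 1e-8)
    res = optimize.minimize(
        nll, [math.log(mean_count * 24.0 / max(durs.mean(), 1e-9)), 0.0],
        method="Nelder-Mead",
    )
    log_m0, logit_p = res.x
    return NullModelFit(
        math.exp(log_m0), 1.0 / (1.0 + math.exp(-logit_p)), -float(res.fun)
    )


# ---------------------------------------------------------------------------
# assembled model and AIC selection


@dataclass
class FittedModel:
    """All four fitted submodels plus the composite likelihood."""

    gravity: GravityParams
    route_choice: RouteChoiceParams
    temporal: TemporalParams
    compliance: ComplianceParams
    log_likelihood: float = math.nan
    n_free: int = 0
    cis: dict[str, ProfileCI] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.log_likelihood


def aic_select(results: Mapping[str, tuple[float, int]]) -> pd.DataFrame:
    """Rank candidate models by AIC.

    ``results`` maps a model name to ``(log_likelihood, n_free_params)``.
    Returns a DataFrame sorted ascending by AIC (ties broken by name) with
    a ``delta_aic`` column.
    """
    rows = [
        {"model": name, "log_likelihood": ll, "k": k, "aic": 2.0 * k - 2.0 * ll}
        for name, (ll, k) in results.items()
    ]
    df = pd.DataFrame(rows).sort_values(["aic", "model"], kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df
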