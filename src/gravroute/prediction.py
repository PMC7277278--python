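"""Flow prediction and model validation metrics.

Given a fitted model, this module predicts origin outflows, destination
inflows (with negative-binomial uncertainty quantiles) and directed
edge-level traffic, and computes two goodness-of-fit measures: a
variance-corrected R^2 on midday station counts and Nagelkerke's
pseudo-R^2 against a non-informative null model.

Edge flows allocate only the admissible share ``(1 - eta_c)`` of the
traffic to specific roads; the inadmissible remainder is location-free by
assumption and is reported as an unallocated total.  Inflow accounting is
lossless: summed destination inflows equal the summed mean OD flows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gravity import nb_count_law
from .network import AdmissiblePathSet
from .routechoice import RouteChoiceParams, choice_probabilities

__all__ = [
    "FlowSummary",
    "predict_flows",
    "share_table",
    "variance_corrected_r2",
    "nagelkerke_pseudo_r2",
]


@dataclass
class FlowSummary:
    """Predicted traffic summaries (all in agents per day)."""

    origin_outflow: pd.Series
    destination_inflow: pd.DataFrame  # columns: mean, q95
    edge_flows: pd.DataFrame  # columns: from, to, flow (directed)
    unallocated: float  # inadmissible-route flow not mapped to edges

    @property
    def total_flow(self) -> float:
        return float(self.origin_outflow.sum())


def predict_flows(
    mu: Mapping[tuple, float],
    path_sets: Mapping[tuple, AdmissiblePathSet],
    route_choice: RouteChoiceParams,
    p: float,
    *,
    quantile: float = 0.95,
) -> FlowSummary:
    """Predict origin outflows, destination inflows and edge traffic.

    Parameters
    ----------
    mu
        Mean daily flow per OD pair.
    path_sets
        Admissible paths per OD pair (used for edge allocation).
    route_choice
        Fitted route-choice parameters; ``eta_c`` controls the unallocated
        inadmissible share.
    p
        Mean-to-variance ratio; the inflow ``q95`` column is the
        ``quantile`` of NB(total inflow, p).
    """
    outflow: dict = {}
    inflow: dict = {}
    edge_flow: dict[tuple, float] = {}
    admissible = 1.0 - route_choice.eta_c
    for (i, j), m in mu.items():
        outflow[i] = outflow.get(i, 0.0) + m
        inflow[j] = inflow.get(j, 0.0) + m
        if m == 0:
            continue
        ps = path_sets[(i, j)]
        if not ps.paths:
            continue
        probs = choice_probabilities(ps, route_choice.lam)
        for path, pr in zip(ps.paths, probs):
            f = m * admissible * pr
            for u, v in path.edges():
                edge_flow[(u, v)] = edge_flow.get((u, v), 0.0) + f

    origin_outflow = pd.Series(outflow, name="outflow").sort_index()
    rows = []
    for j in sorted(inflow):
        mean = inflow[j]
        q95 = float(nb_count_law(mean, p).ppf(quantile))
        rows.append({"destination": j, "mean": mean, "q95": q95})
    destination_inflow = pd.DataFrame(rows).set_index("destination")
    edges = pd.DataFrame(
        [{"from": u, "to": v, "flow": f} for (u, v), f in sorted(edge_flow.items(), key=lambda kv: str(kv[0]))]
    )
    total = float(sum(mu.values()))
    return FlowSummary(
        origin_outflow,
        destination_inflow,
        edges,
        unallocated=route_choice.eta_c * total,
    )


def share_table(values: pd.Series) -> pd.DataFrame:
    """Cumulative share curve: entries sorted descending with the
    cumulative fraction of the total they receive."""
    total = float(values.sum())
    if total <= 0:
        raise ValueError("total flow must be positive")
    ordered = values.sort_values(ascending=False, kind="stable")
    out = pd.DataFrame(
        {
            "value": ordered,
            "share": ordered / total,
            "cumulative_share": ordered.cumsum() / total,
        }
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def variance_corrected_r2(
    observed_means: Sequence[float],
    predicted_means: Sequence[float],
    predicted_sds: Sequence[float],
) -> float:
    """R^2 on station means after normalising by predicted SDs.

    Each station contributes its mean observed midday count and the
    model's predicted mean, both divided by the model-predicted standard
    deviation of the station mean (variance ``mean / (p m)`` over ``m``
    identically distributed shifts) to remove heteroscedasticity.
    """
    obs = np.asarray(observed_means, dtype=float)
    pred = np.asarray(predicted_means, dtype=float)
    sd = np.asarray(predicted_sds, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two stations")
    if np.any(sd <= 0):
        raise ValueError("predicted standard deviations must be positive")
    z_obs = obs / sd
    z_pred = pred / sd
    sse = float(((z_obs - z_pred) ** 2).sum())
    sst = float(((z_obs - z_obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observed values are constant after normalisation")
    return 1.0 - sse / sst


def station_mean_sd(mean_per_shift: float, p: float, n_shifts: int) -> float:
    """Predicted SD of a station's mean count over ``n_shifts`` i.i.d.
    shifts: sqrt(mean / (p * n_shifts))."""
    return math.sqrt(mean_per_shift / (p * n_shifts))


def nagelkerke_pseudo_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's pseudo-R^2 from composite log-likelihoods.

    ``n`` is the number of likelihood cells (shift x OD pairs).  Equals 0
    when the model does not improve on the null; a negative value (model
    worse than null) is returned with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_model < loglik_null:
        warnings.warn("model likelihood below null likelihood; pseudo-R^2 negative")
    num = 1.0 - math.exp((2.0 / n) * (loglik_null - loglik_model))
    den = 1.0 - math.exp((2.0 / n) * loglik_null)
    return num / den
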