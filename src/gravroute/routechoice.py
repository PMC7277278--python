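"""Route-choice probabilities and station passage probabilities.

Conditional on travelling an admissible route, an agent picks path ``P``
with probability proportional to ``l_P**(-lambda)``.  With a small
probability ``eta_c`` the agent instead takes an inadmissible route, in
which case it passes any given survey station with probability ``eta_o``
(the noise model is location-free).  The probability that an agent
travelling i -> j passes station k is therefore

    rho_ijk = (1 - eta_c) * sum_{P admissible, k on P} P(choose P)
              + eta_c * eta_o
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .network import AdmissiblePathSet

__all__ = ["RouteChoiceParams", "choice_probabilities", "station_probability"]

#: hard identifiability bound on the inadmissible-route probability
ETA_C_MAX = 0.05


@dataclass
class RouteChoiceParams:
    """lambda: length exponent; eta_c: probability of an inadmissible
    route (bounded above by 0.05 for identifiability); eta_o: probability
    a given station lies on an inadmissible route (shared across
    stations)."""

    lam: float = 7.4
    eta_c: float = 0.049
    eta_o: float = 0.062

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if not 0 <= self.eta_c <= ETA_C_MAX:
            raise ValueError(f"eta_c must lie in [0, {ETA_C_MAX}]")
        if not 0 <= self.eta_o <= 1:
            raise ValueError("eta_o must lie in [0, 1]")


def choice_probabilities(paths: AdmissiblePathSet | Sequence[float], lam: float) -> np.ndarray:
    """Probability of each admissible path, proportional to length**(-lam).

    Accepts an ``AdmissiblePathSet`` or a plain sequence of path lengths.
    Weights are normalized against the shortest length for numerical
    stability at large ``lam``.
    """
    lengths = (
        paths.lengths() if isinstance(paths, AdmissiblePathSet) else np.asarray(paths, float)
    )
    if lengths.size == 0:
        raise ValueError("empty path set (unreachable OD pair?)")
    if np.any(lengths <= 0):
        raise ValueError("path lengths must be positive")
    w = (lengths / lengths.min()) ** (-float(lam))
    return w / w.sum()


def station_probability(
    paths: AdmissiblePathSet,
    station: Hashable,
    params: RouteChoiceParams,
) -> float:
    """Probability rho_ijk that an i -> j agent passes ``station``."""
    if not paths.paths:
        if paths.unreachable:
            return 0.0
        raise ValueError("empty path set")
    probs = choice_probabilities(paths, params.lam)
    on = np.array([p.contains_station(station) for p in paths.paths])
    admissible_mass = float(probs[on].sum())
    return (1.0 - params.eta_c) * admissible_mass + params.eta_c * params.eta_o


def station_probability_matrix(
    path_sets: Sequence[AdmissiblePathSet],
    stations: Sequence,
    params: RouteChoiceParams,
) -> np.ndarray:
    """rho for many OD pairs at once: array ``(n_od, n_stations)``.

    Unreachable OD pairs get zero probability at every station.
    """
    out = np.zeros((len(path_sets), len(stations)))
    for r, ps in enumerate(path_sets):
        if not ps.paths:
            continue
        probs = choice_probabilities(ps, params.lam)
        incid = ps.station_incidence(stations)
        out[r] = (1.0 - params.eta_c) * probs @ incid + params.eta_c * params.eta_o
    return out
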