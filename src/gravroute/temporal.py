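"""Daily traffic pattern: von Mises density on the 24 h clock.

Traffic density over the day is modelled by a von Mises distribution
rescaled to a 24-hour period: a circular analogue of the normal
distribution with peak time ``theta`` (hours) and concentration ``kappa``
(``kappa = 0`` is uniform traffic; the midday/night density ratio is
``exp(2 kappa)``).  The probability ``tau`` that an agent's passage time
falls inside a survey shift's window is the integral of this density over
the window.

Because survey shifts do not cover all times of day equally, the
parameters are estimated from observed passage times by maximising the
*conditional* likelihood: each observation contributes
``log density(t) - log tau(shift)``, conditioning on the window of the
shift in which it was recorded.  The pattern is assumed independent of the
survey location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .ci import ProfileCI, profile_ci

__all__ = [
    "TemporalParams",
    "SurveyShift",
    "daily_density",
    "window_probability",
    "fit_temporal",
    "TemporalFit",
]

PERIOD = 24.0
_TWO_PI = 2.0 * math.pi
#: kappa cap for degenerate (near point-mass) samples
KAPPA_MAX = 50.0
_KAPPA_TINY = 1e-12


@dataclass
class TemporalParams:
    """theta: peak time of day (hours, circular); kappa: concentration."""

    theta: float = 14.0
    kappa: float = 1.34

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        self.theta = float(self.theta) % PERIOD


@dataclass(frozen=True)
class SurveyShift:
    """One roadside survey shift: station, time window, date.

    ``start``/``end`` are hours of day; ``end <= start`` means the window
    wraps past midnight.  The date only matters for bookkeeping (grouping
    simultaneous shifts in event-level simulation).
    """

    shift_id: str
    station: object
    start: float
    end: float
    date: int = 0

    def __post_init__(self):
        if not (0 <= self.start < PERIOD and 0 <= self.end <= PERIOD):
            raise ValueError("shift times must lie in [0, 24)")

    @property
    def duration(self) -> float:
        d = (self.end - self.start) % PERIOD
        return d if d > 0 else PERIOD

    def contains(self, t: float) -> bool:
        t = t % PERIOD
        if self.end > self.start:
            return self.start <= t <= self.end
        return t >= self.start or t <= self.end


def _angle(t, theta):
    """Map hours to radians relative to the peak."""
    return (np.asarray(t, float) - theta) * (_TWO_PI / PERIOD)


def daily_density(params: TemporalParams, t):
    """Traffic density (per hour) at time of day ``t``."""
    if params.kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if params.kappa < _KAPPA_TINY:
        out = np.full_like(np.asarray(t, float), 1.0 / PERIOD)
        return out if out.ndim else float(out)
    u = _angle(t, params.theta)
    out = stats.vonmises.pdf(u, params.kappa) * (_TWO_PI / PERIOD)
    return out if np.ndim(out) else float(out)


def _cumulative(t, params: TemporalParams):
    """Integral of the daily density from hour 0 to hour ``t`` in [0, 24].

    Uses the von Mises CDF extended periodically (cdf(x + 2 pi k) =
    cdf(x) + k), so differences are exact window integrals.
    """
    t = np.asarray(t, float)
    if params.kappa < _KAPPA_TINY:
        return t / PERIOD

    def g(x):
        u = _angle(x, params.theta)
        k = np.floor((u + math.pi) / _TWO_PI)
        return k + stats.vonmises.cdf(u - _TWO_PI * k, params.kappa)

    return g(t) - g(0.0)


def window_probability(params: TemporalParams, shift: SurveyShift) -> float:
    """Probability tau that a passage time falls in the shift window."""
    s, e = shift.start, shift.end
    if e > s:
        return float(_cumulative(e, params) - _cumulative(s, params))
    if e == s:  # full-day window
        return 1.0
    # wraps midnight: [s, 24) plus [0, e]
    return float(
        1.0 - _cumulative(s, params) + _cumulative(e, params)
    )


# ---------------------------------------------------------------------------
# conditional-likelihood fitting


@dataclass
class TemporalFit:
    params: TemporalParams
    log_likelihood: float
    theta_ci: ProfileCI | None = None
    kappa_ci: ProfileCI | None = None
    n_obs: int = 0
    kappa_capped: bool = False

    @property
    def n_free(self) -> int:
        return 2


class _CondNLL:
    """Conditional negative log-likelihood, sufficient-statistic form.

    sum_i log f(t_i) = n log(1/24) + kappa * (C cos a + S sin a)
                       - n log I0(kappa),
    with a the peak angle and (C, S) the summed cosines/sines of the
    observation angles; the window terms group by distinct shift window.
    """

    def __init__(self, times: np.ndarray, windows: list[tuple[float, float]], counts: np.ndarray):
        ang = np.asarray(times, float) * (_TWO_PI / PERIOD)
        self.n = len(ang)
        self.C = float(np.cos(ang).sum())
        self.S = float(np.sin(ang).sum())
        self.windows = windows
        self.counts = np.asarray(counts, float)

    def __call__(self, x) -> float:
        theta, kappa = float(x[0]), float(x[1])
        if kappa < 0:
            return np.inf
        a = theta * (_TWO_PI / PERIOD)
        log_dens = (
            self.n * math.log(1.0 / PERIOD)
            + kappa * (self.C * math.cos(a) + self.S * math.sin(a))
            - self.n * math.log(special.i0e(kappa))
            - self.n * kappa
        )
        params = TemporalParams(theta % PERIOD, kappa)
        log_tau = 0.0
        for (s, e), m in zip(self.windows, self.counts):
            tau = window_probability(params, SurveyShift("w", None, s, e))
            if tau <= 0:
                return np.inf
            log_tau += m * math.log(tau)
        return -(log_dens - log_tau)


def fit_temporal(
    observations: Sequence[tuple[float, str]],
    shifts: Sequence[SurveyShift],
    *,
    compute_ci: bool = True,
    level: float = 0.95,
) -> TemporalFit:
    """Fit (theta, kappa) to observed passage times by conditional ML.

    Parameters
    ----------
    observations
        ``(time_of_day_hours, shift_id)`` pairs; each shift id must refer
        to a shift in ``shifts`` whose window contains the time.
    shifts
        The survey shifts.  Shifts without observations do not enter the
        likelihood (each term conditions on its own shift window).
    """
    if len(observations) < 2:
        raise ValueError("need at least two observation times")
    by_id = {s.shift_id: s for s in shifts}
    times = []
    window_counts: dict[tuple[float, float], int] = {}
    for t, sid in observations:
        if sid not in by_id:
            raise KeyError(f"observation references unknown shift {sid!r}")
        sh = by_id[sid]
        if not sh.contains(t):
            raise ValueError(f"observation time {t} outside shift {sid!r} window")
        times.append(t % PERIOD)
        key = (sh.start, sh.end)
        window_counts[key] = window_counts.get(key, 0) + 1
    times = np.asarray(times)
    if np.ptp(times) == 0 and len(window_counts) == 1:
        raise ValueError("all observations at a single instant; kappa unbounded")

    nll = _CondNLL(times, list(window_counts), np.array(list(window_counts.values())))

    # moment start: circular mean / resultant length of the raw times
    ang = times * (_TWO_PI / PERIOD)
    C, S = np.cos(ang).mean(), np.sin(ang).mean()
    theta0 = (math.atan2(S, C) / _TWO_PI * PERIOD) % PERIOD
    r = math.hypot(C, S)
    kappa0 = min(max(r * (2.0 - r**2) / (1.0 - r**2 + 1e-12), 0.05), KAPPA_MAX)

    best = None
    for th0 in (theta0, (theta0 + 12.0) % PERIOD):
        res = optimize.minimize(
            nll,
            x0=[th0, kappa0],
            method="L-BFGS-B",
            bounds=[(th0 - 12.0, th0 + 12.0), (0.0, KAPPA_MAX)],
        )
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = float(best.x[0]) % PERIOD
    kappa_hat = float(best.x[1])
    capped = kappa_hat >= KAPPA_MAX - 1e-6
    if capped:
        import warnings

        warnings.warn("kappa estimate hit the cap; observations nearly degenerate")

    fit = TemporalFit(
        TemporalParams(theta_hat, kappa_hat), -best.fun, n_obs=len(times), kappa_capped=capped
    )
    if compute_ci:
        nll_min = float(best.fun)

        def prof_theta(theta):
            res = optimize.minimize_scalar(
                lambda k: nll([theta, k]), bounds=(0.0, KAPPA_MAX), method="bounded"
            )
            return res.fun

        def prof_kappa(kappa):
            res = optimize.minimize_scalar(
                lambda th: nll([th, kappa]),
                bounds=(theta_hat - 12.0, theta_hat + 12.0),
                method="bounded",
            )
            return res.fun

        fit.theta_ci = profile_ci(
            prof_theta, theta_hat, nll_min, theta_hat - 12.0, theta_hat + 12.0, level=level
        )
        fit.kappa_ci = profile_ci(prof_kappa, kappa_hat, nll_min, 0.0, KAPPA_MAX, level=level)
    return fit
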