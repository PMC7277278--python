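"""Profile-likelihood confidence intervals.

An interval endpoint is where the profile log-likelihood has dropped by
``chi2_{1}(level) / 2`` (1.92 for a 95% interval) from its maximum, found
by bracketing and bisection.  If the profile never reaches the drop before
a parameter bound, that side is reported open (as happens for weakly
identified parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize, stats

__all__ = ["ProfileCI", "profile_ci"]


@dataclass
class ProfileCI:
    lower: float
    upper: float
    level: float = 0.95
    lower_open: bool = False
    upper_open: bool = False

    def contains(self, value: float) -> bool:
        lo = -math.inf if self.lower_open else self.lower
        hi = math.inf if self.upper_open else self.upper
        return lo <= value <= hi

    def __iter__(self):
        yield self.lower
        yield self.upper


def _bracket_side(
    profile_nll: Callable[[float], float],
    mle: float,
    target: float,
    bound: float,
    direction: int,
) -> tuple[float, bool]:
    """Find where the profile crosses ``target`` between ``mle`` and
    ``bound``; returns (endpoint, open_flag)."""
    span = abs(bound - mle)
    if span == 0:
        return mle, False
    # march outward geometrically until the profile exceeds the target
    x_in = mle
    dist = max(span * 0.05, 1e-12)
    x = mle
    for _ in range(64):
        x = mle + direction * min(dist, span)
        val = profile_nll(x)
        if np.isfinite(val) and val >= target:
            break
        if dist >= span:
            # never reached the drop before the bound: open side
            return bound, True
        x_in = x
        dist *= 2.0
    else:
        return bound, True

    def gap(y):
        v = profile_nll(y)
        # clip non-finite profile values so bisection still sees the crossing
        return (1e12 if not np.isfinite(v) else v) - target

    try:
        root = optimize.brentq(
            gap, min(x_in, x), max(x_in, x), xtol=1e-6 * max(1.0, abs(mle))
        )
    except ValueError:
        return x, False
    return float(root), False


def profile_ci(
    profile_nll: Callable[[float], float],
    mle: float,
    nll_min: float,
    lower_bound: float,
    upper_bound: float,
    level: float = 0.95,
) -> ProfileCI:
    """Profile-likelihood interval for one parameter.

    Parameters
    ----------
    profile_nll
        Negative profile log-likelihood: the nuisance parameters are
        re-optimised inside this callable.
    mle, nll_min
        Location and value of the minimum.
    lower_bound, upper_bound
        Admissible parameter range; a profile that stays within the drop
        all the way to a bound yields an open side there.
    """
    drop = stats.chi2.ppf(level, df=1) / 2.0
    target = nll_min + drop
    lo, lo_open = _bracket_side(profile_nll, mle, target, lower_bound, -1)
    hi, hi_open = _bracket_side(profile_nll, mle, target, upper_bound, +1)
    return ProfileCI(lo, hi, level, lo_open, hi_open)
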