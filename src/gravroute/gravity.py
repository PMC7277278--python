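"""Gravity model: mean origin-destination flows and the count law.

The mean daily number of agents travelling from origin ``i`` to
destination ``j`` is

    mu_ij = c * m_i * a_j * d_ij**(-alpha_d)

where ``m_i`` (repulsiveness) and ``a_j`` (attractiveness) are composed
from one-covariate *building blocks*: the power form ``f0(x) = x**alpha1``
and the saturating form ``f1(x) = (x / (x + alpha0))**alpha1``.  Products
of blocks express an "and" relation between covariates, sums an "or"
relation.

The applied covariate model is

    mu_ij = c * (pop_i/(pop_i+pop0))**alpha_pop * beta_CA**CA_i
              * (A_j/(A_j+A0))**alpha_A
              * (1 + beta_camp*camp_j + beta_fac*fac_j + beta_mar*mar_j
                   + beta_lpop*(lpop_j/(lpop_j+lpop0))**alpha_lpop)
              * d_ij**(-alpha_d)

with populations in millions, near-lake populations in thousands, lake
areas in km^2 and travel times in units of 1e4 minutes -- parameter values
are only meaningful on these scales.

Counts are negative binomial with a mean-to-variance ratio ``p`` shared
across all OD pairs.  With a shared "success" parameter the family is
closed under addition of independent terms, so predictions are invariant
to how individual origins or destinations are pooled into regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "BuildingBlock",
    "CovariateModel",
    "GravityParams",
    "OriginCovariates",
    "DestinationCovariates",
    "eval_building_block",
    "repulsiveness",
    "attractiveness",
    "mean_flow",
    "nb_count_law",
    "MINUTES_SCALE",
]

#: travel times enter the gravity kernel in units of 1e4 minutes
MINUTES_SCALE = 1e4


@dataclass(frozen=True)
class BuildingBlock:
    """One-covariate factor: power ``x**alpha1`` or saturating
    ``(x/(x+alpha0))**alpha1``."""

    covariate: str
    form: Literal["power", "saturating"] = "power"
    alpha1: float = 1.0
    alpha0: float | None = None

    def __post_init__(self):
        if self.form == "saturating":
            if self.alpha0 is None or not self.alpha0 > 0:
                raise ValueError("saturating form requires alpha0 > 0")
        elif self.form != "power":
            raise ValueError(f"unknown form {self.form!r}")

    def __call__(self, x):
        return eval_building_block(self, x)


def eval_building_block(block: BuildingBlock, x):
    """Evaluate a building block at covariate value(s) ``x >= 0``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("covariate values must be nonnegative")
    if block.form == "power":
        out = x**block.alpha1
    else:
        out = (x / (x + block.alpha0)) ** block.alpha1
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CovariateModel:
    """Sum-of-products composition of building blocks.

    ``terms`` is a list of ``(coefficient_name, blocks)``; each term is the
    product of its blocks times the named scalar coefficient (name ``None``
    means coefficient 1).  ``constant`` adds a leading scalar.  Evaluated
    against a covariate table and a coefficient dictionary the model yields
    one nonnegative value per row.
    """

    terms: tuple[tuple[str | None, tuple[BuildingBlock, ...]], ...]
    constant: float = 0.0

    def coefficient_names(self) -> list[str]:
        return [name for name, _ in self.terms if name is not None]

    def evaluate(self, covariates, coefficients: dict[str, float]):
        total = None
        for name, blocks in self.terms:
            coef = 1.0 if name is None else float(coefficients[name])
            if coef < 0:
                raise ValueError(f"coefficient {name!r} must be nonnegative")
            term = coef
            for b in blocks:
                term = term * b(np.asarray(covariates[b.covariate], dtype=float))
            total = term if total is None else total + term
        if total is None:
            total = 0.0
        return self.constant + total


@dataclass
class GravityParams:
    """Parameters of the applied gravity model (see module docstring).

    Defaults are the fitted values for the British Columbia boater-traffic
    system; the exponents ``alpha_pop``, ``alpha_A`` and ``alpha_lpop``
    are fixed at 1 unless explicitly freed.
    """

    c: float = 3.73e-8
    p: float = 0.23
    alpha_d: float = 3.45
    pop0: float = 0.16
    alpha_pop: float = 1.0
    beta_CA: float = 14.79
    A0: float = 1236.0
    alpha_A: float = 1.0
    beta_camp: float = 6.55
    beta_fac: float = 4.51
    beta_mar: float = 26.4
    beta_lpop: float = 1011.0
    lpop0: float = 888.0
    alpha_lpop: float = 1.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.c > 0:
            raise ValueError("c must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")
        if not self.alpha_d > 0:
            raise ValueError("alpha_d must be positive")
        for name in ("pop0", "A0", "lpop0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("beta_CA", "beta_camp", "beta_fac", "beta_mar", "beta_lpop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def updated(self, **kw) -> "GravityParams":
        return replace(self, **kw)

    @classmethod
    def parameter_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class OriginCovariates:
    """Origin covariates: population in 1e6 persons and a Canada flag."""

    pop: float
    CA: int = 0


@dataclass(frozen=True)
class DestinationCovariates:
    """Destination covariates: lake area (km^2), facility indicators and
    population living near the lake (1e3 persons)."""

    A: float
    camp: int = 0
    fac: int = 0
    mar: int = 0
    lpop: float = 0.0


def repulsiveness(params: GravityParams, origin: OriginCovariates):
    """Origin propensity m_i to emit agents."""
    pop = np.asarray(origin.pop, dtype=float)
    ca = np.asarray(origin.CA, dtype=float)
    sat = (pop / (pop + params.pop0)) ** params.alpha_pop
    return sat * params.beta_CA**ca


def attractiveness(params: GravityParams, dest: DestinationCovariates):
    """Destination propensity a_j: lake size gated by ("and") the facility
    / nearby-population term (an "or" combination)."""
    a = np.asarray(dest.A, dtype=float)
    lpop = np.asarray(dest.lpop, dtype=float)
    size = (a / (a + params.A0)) ** params.alpha_A
    lpop_sat = (lpop / (lpop + params.lpop0)) ** params.alpha_lpop
    amenity = (
        1.0
        + params.beta_camp * np.asarray(dest.camp, dtype=float)
        + params.beta_fac * np.asarray(dest.fac, dtype=float)
        + params.beta_mar * np.asarray(dest.mar, dtype=float)
        + params.beta_lpop * lpop_sat
    )
    return size * amenity


def mean_flow(
    params: GravityParams,
    origin: OriginCovariates,
    dest: DestinationCovariates,
    d_ij,
    *,
    minutes: bool = True,
):
    """Mean daily flow mu_ij.

    ``d_ij`` is the shortest travel time, in minutes by default
    (``minutes=False`` if already on the 1e4-minute scale).  Unreachable
    pairs (infinite distance) yield zero flow.
    """
    d = np.asarray(d_ij, dtype=float)
    if np.any(d <= 0):
        raise ValueError("travel time must be positive")
    if minutes:
        d = d / MINUTES_SCALE
    m = repulsiveness(params, origin)
    a = attractiveness(params, dest)
    with np.errstate(over="ignore"):
        out = np.where(np.isinf(d), 0.0, params.c * m * a * d**-params.alpha_d)
    return out if out.ndim else float(out)


class _PointMassAtZero:
    """Degenerate count distribution for mu = 0."""

    def pmf(self, k):
        k = np.asarray(k)
        out = np.where(k == 0, 1.0, 0.0)
        return out if out.ndim else float(out)

    def logpmf(self, k):
        with np.errstate(divide="ignore"):
            return np.log(self.pmf(k))

    def cdf(self, k):
        k = np.asarray(k)
        out = np.where(k >= 0, 1.0, 0.0)
        return out if out.ndim else float(out)

    def ppf(self, q):
        return np.zeros_like(np.asarray(q, dtype=float))

    def mean(self):
        return 0.0

    def var(self):
        return 0.0

    def rvs(self, size=None, random_state=None):
        return np.zeros(size or 1, dtype=int) if size else 0


def nb_shape(mu, p):
    """Shape parameter r of NB(mean mu, mean/variance ratio p): with
    success parameter p, mean = r(1-p)/p, so r = mu p / (1-p)."""
    return mu * p / (1.0 - p)


def nb_count_law(mu: float, p: float):
    """Count distribution with mean ``mu`` and variance ``mu / p``.

    Returns a frozen scipy distribution: negative binomial with success
    parameter ``p`` (so independent terms with common ``p`` add up to the
    same family), a Poisson for ``p = 1``, and a point mass at zero for
    ``mu = 0``.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    if mu == 0:
        return _PointMassAtZero()
    if p == 1:
        return stats.poisson(mu)
    return stats.nbinom(nb_shape(mu, p), p)


def applied_attractiveness_model(params: GravityParams) -> tuple[CovariateModel, dict]:
    """The applied amenity composition as a generic ``CovariateModel``
    (useful for AIC candidate construction) plus its coefficient values."""
    model = CovariateModel(
        terms=(
            ("beta_camp", (BuildingBlock("camp"),)),
            ("beta_fac", (BuildingBlock("fac"),)),
            ("beta_mar", (BuildingBlock("mar"),)),
            (
                "beta_lpop",
                (
                    BuildingBlock(
                        "lpop", "saturating", params.alpha_lpop, params.lpop0
                    ),
                ),
            ),
        ),
        constant=1.0,
    )
    coefs = {
        "beta_camp": params.beta_camp,
        "beta_fac": params.beta_fac,
        "beta_mar": params.beta_mar,
        "beta_lpop": params.beta_lpop,
    }
    return model, coefs
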