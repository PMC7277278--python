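"""Compliance model: probability that a passing agent yields usable data.

Two rates are estimated from pooled roadside counts.  The participation
rate is the fraction of passing agents that stop,

    xi_p = stopped / (stopped + bypassed),

and the data-quality rate is the fraction of stopped high-risk agents
providing complete and consistent information,

    xi_c = highrisk_complete / highrisk_stopped.

The overall compliance rate is xi = xi_p * xi_c, assumed constant across
agents, survey times and stations (counts may therefore be pooled across
stations before estimation).  Exact (Clopper-Pearson) binomial intervals
are attached to both rates.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .ci import ProfileCI

__all__ = ["ComplianceData", "ComplianceParams", "estimate_compliance"]


@dataclass
class ComplianceData:
    """Pooled compliance counts.

    ``n_stopped``/``n_bypassed`` come from shifts where bypassing traffic
    was tallied; ``n_highrisk_stopped``/``n_highrisk_complete`` from the
    data-quality check of stopped high-risk agents.
    """

    n_stopped: int
    n_bypassed: int
    n_highrisk_stopped: int
    n_highrisk_complete: int

    def __post_init__(self):
        for name in ("n_stopped", "n_bypassed", "n_highrisk_stopped", "n_highrisk_complete"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_highrisk_complete > self.n_highrisk_stopped:
            raise ValueError("complete-data count exceeds stopped high-risk count")

    def __add__(self, other: "ComplianceData") -> "ComplianceData":
        return ComplianceData(
            self.n_stopped + other.n_stopped,
            self.n_bypassed + other.n_bypassed,
            self.n_highrisk_stopped + other.n_highrisk_stopped,
            self.n_highrisk_complete + other.n_highrisk_complete,
        )


@dataclass
class ComplianceParams:
    xi_p: float
    xi_c: float
    xi: float
    xi_p_ci: ProfileCI | None = None
    xi_c_ci: ProfileCI | None = None

    def __post_init__(self):
        for name in ("xi_p", "xi_c", "xi"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _binomial_ci(k: int, n: int, level: float) -> ProfileCI:
    res = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return ProfileCI(float(res.low), float(res.high), level)


def estimate_compliance(data: ComplianceData, level: float = 0.95) -> ComplianceParams:
    """Estimate xi_p, xi_c and xi = xi_p * xi_c with exact binomial CIs."""
    n_passed = data.n_stopped + data.n_bypassed
    if n_passed == 0:
        raise ValueError(
            "no passing agents recorded; pool compliance counts across shifts"
        )
    if data.n_highrisk_stopped == 0:
        raise ValueError(
            "no stopped high-risk agents recorded; pool compliance counts across shifts"
        )
    xi_p = data.n_stopped / n_passed
    xi_c = data.n_highrisk_complete / data.n_highrisk_stopped
    return ComplianceParams(
        xi_p,
        xi_c,
        xi_p * xi_c,
        xi_p_ci=_binomial_ci(data.n_stopped, n_passed, level),
        xi_c_ci=_binomial_ci(data.n_highrisk_complete, data.n_highrisk_stopped, level),
    )
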