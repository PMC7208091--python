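"""Domain types for the reproduction model.

The model views the generative output of a whole plant population collectively:
a resource budget ``R`` is split between ovule production (a proportion
``alpha``, at cost ``r_f`` per ovule) and pollen production (the remainder, at
cost ``r_m`` per pollen).  Retained pollen disperses uniformly over a bounded
range of ``h`` spatial units, each the size of one ovule's pollen-catching
surface, and an ovule is fertilized when at least one pollen lands on its unit.

All quantities are real-valued in the analytic layer; the Monte Carlo
simulator (:mod:`sexalloc.simulate`) is the only place where gamete counts and
the range size are integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ParameterError",
    "DegenerateRangeError",
    "AssumptionViolationError",
    "OptimizationFailureError",
    "InfeasibleTargetError",
    "ResourceBudget",
    "ReproductionParams",
    "DispersalParams",
    "GameteCounts",
    "FertilizationStats",
]


class ParameterError(ValueError):
    """A model parameter violates its admissible range."""


class DegenerateRangeError(ParameterError):
    """The dispersal range is too small for the requested quantity
    (e.g. the empty-unit probability degenerates to 0 at h <= 1)."""


class AssumptionViolationError(ValueError):
    """A structural model assumption (such as h >= F) is violated."""


class OptimizationFailureError(RuntimeError):
    """The optimizer could not locate or confirm the optimum."""


class InfeasibleTargetError(ValueError):
    """A requested fertilization level exceeds the attainable maximum."""

    def __init__(self, target: float, maximum: float):
        self.target = target
        self.maximum = maximum
        super().__init__(
            f"target E(F*)={target:g} exceeds the attainable maximum {maximum:g}"
        )


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class ResourceBudget:
    """Gametic production economy without the allocation decision.

    Parameters
    ----------
    R : float
        Total resources available for gamete production (abstract energy
        units), > 0.
    r_f : float
        Resource investment to produce one ovule, > 0.
    r_m : float
        Resource investment to produce one pollen, > 0 (typically r_m < r_f).
    """

    R: float
    r_f: float
    r_m: float

    def __post_init__(self) -> None:
        _require(self.R > 0, f"R must be > 0, got {self.R}")
        _require(self.r_f > 0, f"r_f must be > 0, got {self.r_f}")
        _require(self.r_m > 0, f"r_m must be > 0, got {self.r_m}")

    def with_allocation(self, alpha: float) -> "ReproductionParams":
        return ReproductionParams(self.R, self.r_f, self.r_m, alpha)

    def scaled(self, q: float) -> "ResourceBudget":
        """Budget after resources decline to q*R."""
        return replace(self, R=q * self.R)

    @property
    def max_ovules(self) -> float:
        return self.R / self.r_f

    @property
    def max_pollen(self) -> float:
        return self.R / self.r_m


@dataclass(frozen=True)
class ReproductionParams(ResourceBudget):
    """Resource budget plus the sexual allocation ``alpha`` in (0, 1):
    the proportion of R invested in ovules; (1-alpha)R goes to pollen."""

    alpha: float

    def __post_init__(self) -> None:
        ResourceBudget.__post_init__(self)
        _require(0 < self.alpha < 1, f"alpha must lie in (0,1), got {self.alpha}")

    @property
    def budget(self) -> ResourceBudget:
        return ResourceBudget(self.R, self.r_f, self.r_m)


@dataclass(frozen=True)
class DispersalParams:
    """Pollen dispersal range and retention.

    Parameters
    ----------
    h : float
        Size of the pollen dispersal range in units of one ovule's
        pollen-catching surface, >= 1.  Real-valued here; the simulator
        requires an integer.
    w : float
        Proportion of produced pollen retained within the range, in (0, 1].
        w = 1 (no loss) is admitted; w = 0 is rejected because it leaves no
        pollen available for fertilization.
    """

    h: float
    w: float = 1.0

    def __post_init__(self) -> None:
        _require(self.h >= 1, f"h must be >= 1, got {self.h}")
        _require(0 < self.w <= 1, f"w must lie in (0,1], got {self.w}")

    @property
    def z(self) -> float:
        """Pollen-catching surface size as a fraction of the range (1/h)."""
        return 1.0 / self.h


@dataclass(frozen=True)
class GameteCounts:
    """Numbers of ovules (F) and pollen (M) produced by the population."""

    F: float
    M: float

    def __post_init__(self) -> None:
        _require(self.F >= 0, f"F must be >= 0, got {self.F}")
        _require(self.M >= 0, f"M must be >= 0, got {self.M}")

    def resources(self, budget: ResourceBudget) -> float:
        """Resources consumed: r_f*F + r_m*M (equals R for valid counts)."""
        return budget.r_f * self.F + budget.r_m * self.M


@dataclass(frozen=True)
class FertilizationStats:
    """Closed-form fertilization summary.

    Attributes
    ----------
    b : float
        Probability that a spatial unit stays empty were the whole retained
        budget spent on pollen: b = (1-1/h)^(wR/r_m).
    E_P : float
        Expected proportion of fertilized ovules, 1 - b^(1-alpha).
    V_P : float | None
        Variance of the fertilized proportion (None when F < 1, where the
        occupancy variance formula has no meaning).
    E_Fstar : float
        Expected number of fertilized ovules, F * E_P.
    SD_Fstar : float | None
        F * sqrt(V_P), the standard-deviation band around E(F*).
    F, M : float
        The gamete counts the statistics refer to.
    """

    b: float
    E_P: float
    V_P: float | None
    E_Fstar: float
    SD_Fstar: float | None
    F: float
    M: float

    def __post_init__(self) -> None:
        _require(0 < self.b < 1, f"b must lie in (0,1), got {self.b}")
        _require(0 <= self.E_P <= 1, f"E_P must lie in [0,1], got {self.E_P}")
        if self.V_P is not None:
            _require(
                -1e-15 <= self.V_P <= 0.25 + 1e-15,
                f"V_P must lie in [0, 0.25], got {self.V_P}",
            )
        if not math.isclose(self.E_Fstar, self.F * self.E_P, rel_tol=1e-12, abs_tol=1e-12):
            raise ParameterError("E_Fstar must equal F * E_P")
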