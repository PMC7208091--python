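"""Compensation of a resource decline R -> qR.

After a decline the population produces F' = qF ovules and M' = qM pollen, so
the expected number of fertilized ovules drops below its previous level.
Three single-parameter adjustments can, under conditions, restore the
baseline E(F*):

* re-allocation — choose a new alpha under qR; feasible iff the baseline lies
  at or below the post-decline maximum, in which case a dual pair of
  allocations achieves it;
* retention — raise the retained fraction w to w'; feasible iff q > E(P) and
  the solved w' does not exceed 1;
* range shrinkage — shrink the dispersal range h to h'; feasible iff
  q > E(P) and the solved h' still holds the qF ovules (h' >= qF).

Both density strategies target the raised proportion E(P') = E(P)/q, which
exactly offsets the factor-q loss of ovules.  Infeasibility is a structured
result, never an exception, so parameter sweeps do not abort.  Every feasible
result's ``achieved_E_Fstar`` is recomputed by forward evaluation of the
adjusted parameters, not read off the inversion formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .core import expected_fertilized, gamete_counts
from .optimize import DualPair, dual_allocations, optimal_allocation
from .params import (
    DispersalParams,
    FertilizationStats,
    GameteCounts,
    ParameterError,
    ReproductionParams,
)

__all__ = [
    "DeclineScenario",
    "CompensationResult",
    "apply_decline",
    "compensable_by_allocation",
    "compensate_retention",
    "compensate_range",
    "compensation_map",
]

Strategy = Literal["allocation", "retention", "range"]


@dataclass(frozen=True)
class DeclineScenario:
    """A resource decline: only a fraction q of the previous budget remains;
    all other parameters are initially unchanged."""

    q: float
    params: ReproductionParams
    disp: DispersalParams

    def __post_init__(self) -> None:
        if not (0 < self.q <= 1):
            raise ParameterError(f"q must lie in (0,1], got {self.q}")

    @property
    def baseline(self) -> FertilizationStats:
        """Fertilization summary before the decline."""
        return expected_fertilized(self.params, self.disp)

    @property
    def declined_params(self) -> ReproductionParams:
        return ReproductionParams(
            self.q * self.params.R, self.params.r_f, self.params.r_m, self.params.alpha
        )


@dataclass(frozen=True)
class CompensationResult:
    strategy: Strategy
    feasible: bool
    adjusted_value: tuple[float, float] | float | None
    achieved_E_Fstar: float | None
    baseline_E_Fstar: float
    infeasibility_reason: str | None = None
    alpha_hat_after: float | None = None  # new optimum (allocation strategy)


def apply_decline(scenario: DeclineScenario) -> tuple[GameteCounts, FertilizationStats]:
    """Gamete counts and fertilization statistics after the decline, with the
    allocation left unchanged: F' = qF, M' = qM, E(P') = 1-(1-1/h)^(wqM)."""
    declined = scenario.declined_params
    return gamete_counts(declined), expected_fertilized(declined, scenario.disp)


def compensable_by_allocation(scenario: DeclineScenario) -> CompensationResult:
    """Compensation by re-allocating the reduced budget.

    Feasible iff baseline E(F*) <= max over alpha of E(F*) under qR.  When
    feasible the two allocations achieving the baseline level (one on each
    side of the new optimum) are returned.
    """
    base = scenario.baseline.E_Fstar
    declined_budget = scenario.params.budget.scaled(scenario.q)
    opt = optimal_allocation(declined_budget, scenario.disp)
    if base > opt.max_E_Fstar * (1.0 + 1e-12):
        return CompensationResult(
            strategy="allocation",
            feasible=False,
            adjusted_value=None,
            achieved_E_Fstar=None,
            baseline_E_Fstar=base,
            infeasibility_reason="exceeds_max_after_decline",
            alpha_hat_after=opt.alpha_hat,
        )
    pair: DualPair = dual_allocations(
        min(base, opt.max_E_Fstar), declined_budget, scenario.disp
    )
    achieved = expected_fertilized(
        declined_budget.with_allocation(pair.alpha_1), scenario.disp
    ).E_Fstar
    return CompensationResult(
        strategy="allocation",
        feasible=True,
        adjusted_value=(pair.alpha_1, pair.alpha_2),
        achieved_E_Fstar=achieved,
        baseline_E_Fstar=base,
        alpha_hat_after=opt.alpha_hat,
    )


def _density_preconditions(scenario: DeclineScenario) -> tuple[float, float, float]:
    """Shared setup for the two density strategies: baseline E(P), M, F."""
    counts = gamete_counts(scenario.params)
    stats = scenario.baseline
    return stats.E_P, counts.M, counts.F


def compensate_retention(scenario: DeclineScenario) -> CompensationResult:
    """Compensation by raising pollen retention w -> w'.

    Solves 1-(1-1/h)^(w' q M) = E(P)/q, giving
    w' = ln(1 - E(P)/q) / (qM ln(1-1/h)).  Requires q > E(P) (else the target
    proportion exceeds 1) and w' <= 1.
    """
    E_P, M, _ = _density_preconditions(scenario)
    base = scenario.baseline.E_Fstar
    q = scenario.q
    if q <= E_P:
        return CompensationResult(
            "retention", False, None, None, base, "decline_too_severe"
        )
    w_prime = math.log(1.0 - E_P / q) / (q * M * math.log1p(-1.0 / scenario.disp.h))
    if w_prime > 1.0 + 1e-12:
        return CompensationResult(
            "retention", False, w_prime, None, base, "retention_ceiling"
        )
    w_prime = min(w_prime, 1.0)
    achieved = expected_fertilized(
        scenario.declined_params, DispersalParams(h=scenario.disp.h, w=w_prime)
    ).E_Fstar
    return CompensationResult("retention", True, w_prime, achieved, base)


def compensate_range(
    scenario: DeclineScenario, round_up: bool = False
) -> CompensationResult:
    """Compensation by shrinking the dispersal range h -> h'.

    Solves 1-(1-1/h')^(w q M) = E(P)/q, giving
    h' = 1 / (1 - (1 - E(P)/q)^(1/(w q M))).  Requires q > E(P) and h' >= qF
    (the fewer ovules must still fit in the shrunken range).  ``round_up``
    returns the next integer h' for hand-off to the simulator.
    """
    E_P, M, F = _density_preconditions(scenario)
    base = scenario.baseline.E_Fstar
    q = scenario.q
    if q <= E_P:
        return CompensationResult("range", False, None, None, base, "decline_too_severe")
    h_prime = 1.0 / (1.0 - (1.0 - E_P / q) ** (1.0 / (scenario.disp.w * q * M)))
    if h_prime < q * F * (1.0 - 1e-12):
        return CompensationResult(
            "range", False, h_prime, None, base, "range_below_ovule_count"
        )
    if round_up:
        h_prime = float(math.ceil(h_prime))
    achieved = expected_fertilized(
        scenario.declined_params, DispersalParams(h=h_prime, w=scenario.disp.w)
    ).E_Fstar
    return CompensationResult("range", True, h_prime, achieved, base)


def compensation_map(
    params: ReproductionParams,
    w_grid: Iterable[float],
    h_grid: Iterable[float],
    q: float,
) -> pd.DataFrame:
    """Feasibility of the two density strategies over a (w, h) grid.

    One row per grid cell with columns (w, h, E_P, retention_feasible,
    w_prime, range_feasible, h_prime).  Cells violating h >= F are rejected.
    """
    rows = []
    for h in h_grid:
        for w in w_grid:
            disp = DispersalParams(h=h, w=w)
            scen = DeclineScenario(q=q, params=params, disp=disp)
            ret = compensate_retention(scen)
            rng = compensate_range(scen)
            rows.append(
                {
                    "w": w,
                    "h": h,
                    "E_P": scen.baseline.E_P,
                    "retention_feasible": ret.feasible,
                    "w_prime": ret.adjusted_value if ret.adjusted_value is not None else math.nan,
                    "range_feasible": rng.feasible,
                    "h_prime": rng.adjusted_value if rng.adjusted_value is not None else math.nan,
                }
            )
    return pd.DataFrame(rows)
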