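"""Optimal sexual allocation and its dual solutions.

The expected number of fertilized ovules

    E(F*)(alpha) = (alpha R / r_f) * (1 - b^(1-alpha)),   b = (1-1/h)^(wR/r_m)

is strictly concave in alpha on (0,1) with a unique interior maximizer
``alpha_hat`` characterized by the stationarity condition

    b^(1-alpha) * (alpha * ln b - 1) + 1 = 0.

No closed-form root exists, so the root is bracketed and solved numerically
and always cross-checked against direct bounded maximization of E(F*).
Concavity also yields duality: every attainable level below the maximum is
reached by exactly two allocations, one on either side of alpha_hat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .core import compound_b, expected_fertilized
from .params import (
    DispersalParams,
    InfeasibleTargetError,
    OptimizationFailureError,
    ResourceBudget,
)

__all__ = [
    "OptimumResult",
    "DualPair",
    "implicit_optimality",
    "optimal_allocation",
    "max_expected_fertilized",
    "dual_allocations",
    "optimum_sensitivity",
]

_EPS = 1e-9


@dataclass(frozen=True)
class OptimumResult:
    """Optimal allocation and the maximum it achieves.

    ``residual`` is the value of the implicit optimality equation at
    ``alpha_hat`` (machine-zero at an interior optimum).  ``bound_active`` is
    True when the structural constraint F <= h truncated the admissible
    interval and the optimum sits on that boundary; the interior stationarity
    condition then does not apply and ``residual`` reports the boundary value.
    """

    alpha_hat: float
    max_E_Fstar: float
    residual: float
    b: float
    bound_active: bool = False


@dataclass(frozen=True)
class DualPair:
    """The two allocations alpha_1 <= alpha_hat <= alpha_2 achieving a common
    expected number of fertilized ovules ``target``."""

    alpha_1: float
    alpha_2: float
    target: float


def implicit_optimality(alpha: float, b: float) -> float:
    """Left-hand side of the stationarity condition b^(1-a)(a ln b - 1) + 1.

    Equals d E(F*) / d alpha up to the positive factor R/r_f, so its root is
    the interior maximizer.
    """
    return b ** (1.0 - alpha) * (alpha * math.log(b) - 1.0) + 1.0


def _efstar(alpha: float, budget: ResourceBudget, b: float) -> float:
    return alpha * budget.R / budget.r_f * (-math.expm1((1.0 - alpha) * math.log(b)))


def _alpha_upper(budget: ResourceBudget, disp: DispersalParams) -> float:
    """Upper end of the admissible allocation interval: alpha <= h*r_f/R keeps
    the ovule count within the h spatial units."""
    return min(1.0 - _EPS, disp.h * budget.r_f / budget.R)


def optimal_allocation(budget: ResourceBudget, disp: DispersalParams) -> OptimumResult:
    """Locate the unique optimal allocation alpha_hat.

    Solves the implicit optimality equation by bracketed root finding on
    (0, 1); the root is cross-validated against bounded scalar maximization of
    E(F*) (agreement to 1e-8 required).  When the constraint alpha <= h*r_f/R
    binds, the optimum is the boundary allocation (E(F*) is increasing up to
    the interior root).
    """
    b = compound_b(budget.with_allocation(0.5), disp)
    lo, hi = _EPS, 1.0 - _EPS
    g_lo, g_hi = implicit_optimality(lo, b), implicit_optimality(hi, b)
    if not (g_lo > 0 > g_hi):
        raise OptimizationFailureError(
            "implicit optimality equation has no sign change on "
            f"({lo:g},{hi:g}): g({lo:g})={g_lo:g}, g({hi:g})={g_hi:g}"
        )
    root = brentq(implicit_optimality, lo, hi, args=(b,), xtol=1e-12, rtol=1e-15)

    upper = _alpha_upper(budget, disp)
    res = minimize_scalar(
        lambda a: -_efstar(a, budget, b),
        bounds=(lo, upper),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover - bounded Brent does not fail here
        raise OptimizationFailureError(f"bounded maximization failed: {res.message}")

    if root > upper:
        # structural bound F <= h binds; concavity puts the optimum at the boundary
        alpha_hat = upper
        bound_active = True
    else:
        alpha_hat = root
        bound_active = False
        if abs(res.x - root) > 1e-8:
            raise OptimizationFailureError(
                f"implicit-equation root {root!r} and direct maximizer {res.x!r} "
                "disagree beyond 1e-8"
            )
    return OptimumResult(
        alpha_hat=alpha_hat,
        max_E_Fstar=_efstar(alpha_hat, budget, b),
        residual=implicit_optimality(alpha_hat, b),
        b=b,
        bound_active=bound_active,
    )


def max_expected_fertilized(budget: ResourceBudget, disp: DispersalParams) -> float:
    """Maximum expected number of fertilized ovules over all allocations."""
    opt = optimal_allocation(budget, disp)
    return expected_fertilized(budget.with_allocation(opt.alpha_hat), disp).E_Fstar


def dual_allocations(
    target: float, budget: ResourceBudget, disp: DispersalParams
) -> DualPair:
    """The two allocations achieving a given expected fertilized-ovule level.

    Concavity of E(F*) in alpha guarantees exactly one solution on each side
    of alpha_hat for every 0 < target < max; target == max returns the
    degenerate pair (alpha_hat, alpha_hat).
    """
    if target <= 0:
        raise InfeasibleTargetError(target, 0.0)
    opt = optimal_allocation(budget, disp)
    if target > opt.max_E_Fstar * (1.0 + 1e-12):
        raise InfeasibleTargetError(target, opt.max_E_Fstar)
    if target >= opt.max_E_Fstar * (1.0 - 1e-12):
        return DualPair(opt.alpha_hat, opt.alpha_hat, opt.max_E_Fstar)

    b = opt.b

    def gap(a: float) -> float:
        return _efstar(a, budget, b) - target

    a1 = brentq(gap, _EPS, opt.alpha_hat, xtol=1e-14, rtol=1e-15, maxiter=200)
    upper = _alpha_upper(budget, disp)
    if gap(upper) > 0:
        raise OptimizationFailureError(
            "no upper dual allocation: E(F*) still exceeds the target at the "
            f"admissible boundary alpha={upper:g} (constraint h >= F)"
        )
    a2 = brentq(gap, opt.alpha_hat, upper, xtol=1e-14, rtol=1e-15, maxiter=200)
    return DualPair(a1, a2, target)


def optimum_sensitivity(
    budget: ResourceBudget,
    disp: DispersalParams,
    parameter_name: str,
    grid: Iterable[float],
) -> pd.DataFrame:
    """alpha_hat and max E(F*) along a grid of one parameter.

    ``parameter_name`` is one of R, r_f, r_m, w, h.  The optimum shifts
    further towards ovules when resources grow (R up), pollen gets cheaper
    (r_m down), the range shrinks (h down) or retention rises (w up).
    """
    if parameter_name not in {"R", "r_f", "r_m", "w", "h"}:
        raise ValueError(f"unknown parameter {parameter_name!r}")
    rows = []
    for value in grid:
        kw = {"R": budget.R, "r_f": budget.r_f, "r_m": budget.r_m}
        dk = {"h": disp.h, "w": disp.w}
        (kw if parameter_name in kw else dk)[parameter_name] = value
        opt = optimal_allocation(
            ResourceBudget(kw["R"], kw["r_f"], kw["r_m"]),
            DispersalParams(h=dk["h"], w=dk["w"]),
        )
        rows.append(
            {
                "param_value": value,
                "alpha_hat": opt.alpha_hat,
                "max_E_Fstar": opt.max_E_Fstar,
                "residual": opt.residual,
            }
        )
    return pd.DataFrame(rows)
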