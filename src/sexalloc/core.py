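"""Closed-form layer: gamete counts, pollen density, occupancy probabilities.

Everything here is deterministic arithmetic on the model parameters.  Powers
of (1 - 1/h) are evaluated as exp(exponent * log1p(-1/h)) so that large h and
large pollen numbers do not lose precision.
"""

from __future__ import annotations

import math

from .params import (
    AssumptionViolationError,
    DegenerateRangeError,
    DispersalParams,
    FertilizationStats,
    GameteCounts,
    ParameterError,
    ReproductionParams,
)

__all__ = [
    "gamete_counts",
    "alpha_from_ratios",
    "pollen_density",
    "compound_b",
    "expected_proportion",
    "variance_proportion",
    "variance_proportion_alt",
    "expected_fertilized",
]


def gamete_counts(params: ReproductionParams) -> GameteCounts:
    """Numbers of ovules and pollen under allocation ``alpha``.

    F = alpha*R/r_f and M = (1-alpha)*R/r_m, so that the resource budget is
    exactly exhausted: r_f*F + r_m*M = R.
    """
    F = params.alpha * params.R / params.r_f
    M = (1.0 - params.alpha) * params.R / params.r_m
    return GameteCounts(F=F, M=M)


def alpha_from_ratios(pollen_ovule_ratio: float, cost_ratio: float) -> float:
    """Sexual allocation from the two pollen-ovule ratios.

    Parameters
    ----------
    pollen_ovule_ratio : float
        M/F, the ratio of pollen to ovule numbers, > 0.
    cost_ratio : float
        r_m/r_f, the ratio of per-pollen to per-ovule investment, > 0.

    Returns
    -------
    float
        alpha = 1 / (1 + (r_m/r_f)*(M/F)), in (0, 1).
    """
    if not (pollen_ovule_ratio > 0 and math.isfinite(pollen_ovule_ratio)):
        raise ParameterError(
            f"pollen_ovule_ratio must be finite and > 0, got {pollen_ovule_ratio}"
        )
    if not (cost_ratio > 0 and math.isfinite(cost_ratio)):
        raise ParameterError(f"cost_ratio must be finite and > 0, got {cost_ratio}")
    return 1.0 / (1.0 + cost_ratio * pollen_ovule_ratio)


def pollen_density(M: float, disp: DispersalParams) -> float:
    """Mean number of retained pollen settling per spatial unit: d = w*M/h."""
    if M < 0:
        raise ParameterError(f"M must be >= 0, got {M}")
    return disp.w * M / disp.h


def _pow_1m1h(h: float, exponent: float) -> float:
    """(1 - 1/h)**exponent, numerically stable for large h."""
    return math.exp(exponent * math.log1p(-1.0 / h))


def compound_b(params: ReproductionParams, disp: DispersalParams) -> float:
    """The compound variable b = (1-1/h)^(wR/r_m).

    b is the probability that a given spatial unit stays empty were all of
    the resources allocated to pollen (and the retained fraction w of it
    dispersed).  It lets E(P) collapse to 1 - b^(1-alpha).
    """
    if disp.h <= 1:
        raise DegenerateRangeError(
            f"compound b requires h > 1 (b degenerates to 0 at h={disp.h})"
        )
    return _pow_1m1h(disp.h, disp.w * params.R / params.r_m)


def expected_proportion(M: float, disp: DispersalParams) -> float:
    """Expected proportion of fertilized ovules, E(P) = 1 - (1-1/h)^(wM).

    This is the occupancy probability that at least one of the wM uniformly
    dispersed pollen lands in any given spatial unit.  At the degenerate
    range h = 1 every pollen lands in the single unit, so E(P) = 1 whenever
    wM > 0 (limit convention), and 0 when M = 0.
    """
    if M < 0:
        raise ParameterError(f"M must be >= 0, got {M}")
    if M == 0:
        return 0.0
    if disp.h == 1:
        return 1.0
    return -math.expm1(disp.w * M * math.log1p(-1.0 / disp.h))


def variance_proportion(F: float, M: float, disp: DispersalParams) -> float:
    """Variance V(P) of the fertilized proportion.

    V(P) = (1-1/F)(1-2/h)^(wM) - (1-1/h)^(wM) [ (1-1/h)^(wM) - 1/F ]

    Requires F >= 1 and h > 2 (the two-unit empty probability degenerates
    otherwise).  At F = 1 this reduces to the Bernoulli variance x(1-x) with
    x = (1-1/h)^(wM).
    """
    if F < 1:
        raise ParameterError(f"variance requires F >= 1, got F={F}")
    if disp.h <= 2:
        raise DegenerateRangeError(f"variance requires h > 2, got h={disp.h}")
    wM = disp.w * M
    x1 = _pow_1m1h(disp.h, wM)  # one unit empty
    x2 = math.exp(wM * math.log1p(-2.0 / disp.h))  # two given units empty
    return (1.0 - 1.0 / F) * x2 - x1 * (x1 - 1.0 / F)


def variance_proportion_alt(F: float, M: float, disp: DispersalParams) -> float:
    """Algebraically equivalent second form of V(P):

    (1/F)[(1-1/h)^(wM) - (1-2/h)^(wM)] - [(1-1/h)^(2wM) - (1-2/h)^(wM)]
    """
    if F < 1:
        raise ParameterError(f"variance requires F >= 1, got F={F}")
    if disp.h <= 2:
        raise DegenerateRangeError(f"variance requires h > 2, got h={disp.h}")
    wM = disp.w * M
    x1 = _pow_1m1h(disp.h, wM)
    x2 = math.exp(wM * math.log1p(-2.0 / disp.h))
    return (x1 - x2) / F - (x1 * x1 - x2)


def expected_fertilized(
    params: ReproductionParams, disp: DispersalParams
) -> FertilizationStats:
    """Full closed-form summary, centred on E(F*) = F * E(P) = (alpha R / r_f)(1 - b^(1-alpha)).

    Enforces the structural assumption h >= F (at most one ovule per spatial
    unit, all ovules inside the range).  V(P) and the SD band are populated
    when F >= 1 and h > 2, else left as None.
    """
    counts = gamete_counts(params)
    if counts.F > disp.h * (1 + 1e-12):
        raise AssumptionViolationError(
            f"model assumption h >= F violated: F={counts.F:g} > h={disp.h:g}"
        )
    b = compound_b(params, disp)
    E_P = -math.expm1((1.0 - params.alpha) * math.log(b))
    E_Fstar = counts.F * E_P
    if counts.F >= 1 and disp.h > 2:
        # the continuous relaxation of the variance can dip microscopically
        # below 0 when fewer than one pollen is retained; clamp to a variance
        V_P = max(variance_proportion(counts.F, counts.M, disp), 0.0)
        SD = counts.F * math.sqrt(V_P)
    else:
        V_P = None
        SD = None
    return FertilizationStats(
        b=b, E_P=E_P, V_P=V_P, E_Fstar=E_Fstar, SD_Fstar=SD, F=counts.F, M=counts.M
    )
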