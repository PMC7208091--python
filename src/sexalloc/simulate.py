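"""Monte Carlo balls-in-bins oracle for pollen dispersal and fertilization.

Each replicate scatters the retained pollen uniformly and independently over
the h spatial units of the dispersal range and counts how many of the F
ovule-bearing units receive at least one pollen.  Because dispersal is
uniform, the ovule units are exchangeable with all other units, so the joint
occupancy of the F ovule cells given n retained pollen is obtained directly
from a multinomial over F + 1 cells (F cells of probability 1/h each and one
"elsewhere" cell of probability 1 - F/h) — exact by the aggregation property
of the multinomial, and far cheaper than materializing all h cells.  A
per-pollen full-occupancy path (`_simulate_full`) is kept as an independent
cross-check of that aggregation.

Retention modes
---------------
stochastic (default)
    Each of the M pollen independently stays within the range with
    probability w (binomial thinning; mean retained count exactly wM).
deterministic
    A fixed round(wM) pollen are retained in every replicate, which makes the
    closed forms with exponent round(wM) the exact comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import AssumptionViolationError, DispersalParams, ParameterError, ReproductionParams

__all__ = ["SimulationResult", "simulate_dispersal", "simulate_expected_fertilized"]

_CHUNK = 20_000  # replicates per multinomial block (memory cap)


@dataclass(frozen=True)
class SimulationResult:
    reps: int
    seed: int
    F: int
    M: int
    samples_P: np.ndarray = field(repr=False)
    mean_P: float
    var_P: float
    mean_Fstar: float
    se_mean_P: float


def _as_int(name: str, value: float) -> int:
    if value != int(value):
        raise ParameterError(f"{name} must be an integer in the simulator, got {value}")
    return int(value)


def simulate_dispersal(
    F: int,
    M: int,
    disp: DispersalParams,
    reps: int = 10_000,
    seed: int = 0,
    retention: str = "stochastic",
) -> SimulationResult:
    """Empirical distribution of the fertilized proportion P.

    Parameters
    ----------
    F, M : int
        Ovule and pollen counts (1 <= F <= h, M >= 0).
    disp : DispersalParams
        Range size h (integer here) and retention w.
    reps, seed : int
        Replicate count and RNG seed; the same seed reproduces the samples
        bit-for-bit.
    retention : {"stochastic", "deterministic"}
        Binomial thinning of M at probability w, or a fixed round(w*M).
    """
    F = _as_int("F", F)
    M = _as_int("M", M)
    h = _as_int("h", disp.h)
    if not 1 <= F <= h:
        raise AssumptionViolationError(f"need 1 <= F <= h, got F={F}, h={h}")
    if M < 0 or reps < 1:
        raise ParameterError("M must be >= 0 and reps >= 1")
    if retention not in ("stochastic", "deterministic"):
        raise ParameterError(f"unknown retention mode {retention!r}")

    rng = np.random.default_rng(seed)
    if retention == "stochastic":
        retained = rng.binomial(M, disp.w, size=reps)
    else:
        retained = np.full(reps, round(disp.w * M), dtype=np.int64)

    # ovule cells each 1/h, plus one aggregate cell for the rest of the range
    pvals = np.full(F + 1, 1.0 / h)
    pvals[-1] = 1.0 - F / h
    fertilized = np.empty(reps, dtype=np.int64)
    for start in range(0, reps, _CHUNK):
        stop = min(start + _CHUNK, reps)
        counts = rng.multinomial(retained[start:stop], pvals)
        fertilized[start:stop] = np.count_nonzero(counts[:, :F], axis=1)

    samples_P = fertilized / F
    mean_P = float(samples_P.mean())
    var_P = float(samples_P.var(ddof=1)) if reps > 1 else 0.0
    return SimulationResult(
        reps=reps,
        seed=seed,
        F=F,
        M=M,
        samples_P=samples_P,
        mean_P=mean_P,
        var_P=var_P,
        mean_Fstar=F * mean_P,
        se_mean_P=float(np.sqrt(var_P / reps)),
    )


def _simulate_full(
    F: int,
    M: int,
    disp: DispersalParams,
    reps: int,
    seed: int,
    ovule_units: np.ndarray | None = None,
    retention: str = "deterministic",
) -> np.ndarray:
    """Slow reference path: draw a landing unit for every pollen and read the
    occupancy of explicitly designated ovule units.  Returns the fertilized
    counts per replicate.  Used to cross-check the aggregated multinomial path
    and the exchangeability of unit designation."""
    h = int(disp.h)
    units = np.arange(F) if ovule_units is None else np.asarray(ovule_units)
    if len(units) != F or len(np.unique(units)) != F or units.min() < 0 or units.max() >= h:
        raise ParameterError("ovule_units must be F distinct unit indices in [0, h)")
    rng = np.random.default_rng(seed)
    is_ovule = np.zeros(h, dtype=bool)
    is_ovule[units] = True
    out = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        n = rng.binomial(M, disp.w) if retention == "stochastic" else round(disp.w * M)
        landing = rng.integers(0, h, size=n)
        occupied = np.zeros(h, dtype=bool)
        occupied[landing] = True
        out[r] = int(np.count_nonzero(occupied & is_ovule))
    return out


def simulate_expected_fertilized(
    params: ReproductionParams,
    disp: DispersalParams,
    reps: int = 10_000,
    seed: int = 0,
    retention: str = "stochastic",
) -> SimulationResult:
    """Simulate E(F*) for a full parameter set.

    Gamete counts are rounded to the nearest integers before simulation (the
    analytic layer keeps them continuous).
    """
    F = round(params.alpha * params.R / params.r_f)
    M = round((1.0 - params.alpha) * params.R / params.r_m)
    if F == 0:
        # no whole ovule: F* is identically zero; P is taken as 0 by convention
        zeros = np.zeros(reps)
        return SimulationResult(
            reps=reps, seed=seed, F=0, M=M, samples_P=zeros,
            mean_P=0.0, var_P=0.0, mean_Fstar=0.0, se_mean_P=0.0,
        )
    return simulate_dispersal(F, M, disp, reps=reps, seed=seed, retention=retention)
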