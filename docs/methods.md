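# Methods

## Model and assumptions

The package models the generative phase of reproduction of a plant
population collectively, ignoring individual variation: only population
totals of ovules (`F`) and pollen (`M`) matter.  The assumptions, in order of
appearance:

1. **Fixed budget, linear costs.**  All gametic production resources `R` are
   spent; one ovule costs `r_f`, one pollen `r_m` (typically `r_m < r_f`),
   so `F = αR/r_f` and `M = (1−α)R/r_m` for an allocation `α ∈ (0,1)`.
   Equivalently, `α` is determined by the two pollen–ovule ratios:
   `α = 1/(1 + (r_m/r_f)(M/F))`.
2. **Uniform dispersal over a bounded range.**  The range is partitioned into
   `h` units of one pollen-catching-surface size (`z = 1/h`); a fraction `w`
   of the pollen stays inside and each retained pollen lands independently
   and uniformly on one unit.  There are no spatial coordinates, no
   distance kernels and no per-plant pollen sources — uniformity makes the
   ovules' positions irrelevant.
3. **At most one ovule per unit, all ovules inside the range** (`h ≥ F`),
   enforced as a hard error in `expected_fertilized` and the simulator and as
   the domain bound `α ≤ h·r_f/R` in the optimizer.
4. **Threshold-1 fertilization.**  An ovule is fertilized when at least one
   pollen lands on its unit.  (A general minimum-count rule is conceivable;
   only the ≥1 rule is implemented, as everywhere in the closed forms.)

These give the occupancy forms `E(P) = 1−(1−1/h)^{wM} = 1−b^{1−α}` with
`b = (1−1/h)^{wR/r_m}`, the two-term variance `V(P)`, and
`E(F*) = F·E(P)`.

## Parameters

| name  | meaning                                   | units            | admissible |
|-------|-------------------------------------------|------------------|------------|
| `R`   | gametic production resources              | energy (abstract)| > 0        |
| `r_f` | investment per ovule                      | same as `R`      | > 0        |
| `r_m` | investment per pollen                     | same as `R`      | > 0        |
| `α`   | proportion of `R` invested in ovules      | –                | (0, 1)     |
| `h`   | dispersal-range size                      | catching surfaces| ≥ 1        |
| `w`   | pollen retention within the range         | –                | (0, 1]     |
| `q`   | resources remaining after a decline       | –                | (0, 1]     |

`w = 1` is admitted (every standard illustration uses it) although the
lossless case is a boundary of the model's motivation; `w = 0` is rejected.
`F`, `M` and `h` are real-valued throughout the analytic layer — the formulas
are continuous and the optimum/compensation solutions are generally
non-integer (a solved range size of 742.7 units is meaningful as a model
quantity).  Integerization happens only at the simulator boundary
(`round`, and `ceil` for the optional hand-off of a solved `h′`).

## Numerical choices

* Powers of `(1−1/h)` are computed as `exp(x·log1p(−1/h))` and survival
  complements with `expm1`, keeping 1e−12-level agreement between the two
  printed forms of `V(P)` even for `h ~ 1e6`.
* `h = 1` limit convention: `E(P) = 1` when `wM > 0` (all pollen land on the
  single unit); `h ≤ 1` is a degenerate-range error where `b` would be 0.
* The optimizer brackets the stationarity function on `(1e−9, 1−1e−9)` —
  a sign change is guaranteed since it starts at `1−b > 0` and ends at
  `ln b < 0` — and solves with Brent's method (`xtol = 1e−12`).  Because no
  closed form exists, every root is cross-checked against bounded scalar
  maximization of `E(F*)`; disagreement beyond 1e−8 raises.  When the bound
  `α ≤ h·r_f/R` binds, concavity puts the optimum at the boundary and the
  result is flagged `bound_active`.
* Dual allocations are found by bracketed root finding of `E(F*) − target`
  independently on each side of `α̂`; strict concavity makes each side
  monotone, so no tie-breaking is needed.  A target above the maximum raises
  a structured infeasible-target error reporting the maximum.
* Compensation inversions (`w′`, `h′`) are closed-form, but the *reported*
  achieved expectation always comes from forward re-evaluation of the
  adjusted parameters — the assumption-free arbiter.  Infeasibility is a
  result object with a reason code (`decline_too_severe`,
  `retention_ceiling`, `range_below_ovule_count`,
  `exceeds_max_after_decline`), never an exception, so grid sweeps don't
  abort.
* Under the continuous relaxation the variance formula can dip
  microscopically below zero when fewer than one pollen is retained
  (`wM < 1`, small `h`); `expected_fertilized` clamps it at 0.  The raw
  formula value is still available from `variance_proportion`.

## Simulator

`simulate_dispersal` is the independent oracle for the occupancy formulas:
per replicate it draws the retained pollen count, scatters it uniformly and
counts ovule units with ≥ 1 pollen.  Two retention modes exist because the
model statement ("a proportion w of the M pollen remains") is silent on the
mechanism:

* **stochastic** (default): binomial thinning of `M` at probability `w`,
  mean exactly `wM`.  Its exact occupancy probability is `1−(1−w/h)^M`,
  which differs from the closed form `1−(1−1/h)^{wM}` by `O(Mw(1−w)/h²)` —
  negligible at realistic sizes but not identically zero.
* **deterministic**: a fixed `round(wM)` pollen per replicate, making
  `1−(1−1/h)^{round(wM)}` the *exact* comparator; the closed-form agreement
  tests use this mode.

Occupancy of the `F` ovule units is sampled from a multinomial over `F+1`
cells (`F` cells of probability `1/h`, one aggregate "elsewhere" cell) —
exact by the aggregation property of the multinomial and far cheaper than
materializing all `h` cells.  A per-pollen full-occupancy path with
explicitly designated ovule units is kept as a cross-check; a fixed-seed
two-sample KS test confirms the aggregated path and the exchangeability of
unit designation.  Replicates are processed in 20 000-replicate blocks to
cap memory; results are bit-for-bit reproducible for a given seed.

The simulator emulates exactly the model's idealizations — uniform landing,
independent pollen, collective gamete pools.  Passing tests therefore
validate the mathematics, not the realism: real dispersal is
distance-dependent and anisotropic, real ovule placement is clustered, and
real retention varies with weather.  Agreement says the closed forms are
right *given* the assumptions, nothing more.

## Design decisions that were genuinely open

* **Feasibility conditions as stated, verified forward.**  The appendix-level
  proofs behind the density-strategy conditions are not reproduced; the
  conditions (`q > E(P)`; `w′ ≤ 1`; `h′ ≥ qF`) are implemented literally and
  every feasible verdict is confirmed by forward evaluation, which holds
  regardless of the proofs.
* **Re-allocation after decline** returns the dual pair bracketing the *new*
  optimum, with the new `α̂` reported alongside, so callers can tell the
  moderate from the drastic adjustment whichever side the old allocation was
  on.
* **Illustration parameter sets.**  The first four standard illustrations
  carry complete parameter sets and are reproduced as data tables by
  `run_figure_table`.  The retention/range sweep and the (w, h) feasibility
  map do not print complete sets, so those tables require explicit overrides
  and the printed thresholds (w = 0.65, h = 435/466, h′ = 71.5) are treated
  as unverifiable; only their structure (a single retention ceiling, a single
  minimum feasible range) is asserted, and it reproduces.  Likewise the
  advertised re-allocation example (α° = 0.35, q = 0.8 at h = 10000) fails
  its own feasibility condition numerically (baseline 48.6 > post-decline
  maximum 36.3) but holds at h = 1000 (168.2 ≤ 196.5), which suggests a
  misprinted range size; the tested example uses the verifiable variant.

## Problem sizes

The closed forms and optimizer are microsecond-scale, so tests use them
freely.  Monte Carlo validation runs 1e5 replicates per parameter set
(20 sets) — standard errors of order 1e−4 on `E(P)`, small enough that the
3-SE criterion is informative; the property suites use 100–1000 randomized
parameter sets and 200 randomized decline scenarios.

## Known limitations

* One ovule per catching surface; species with multiple ovules per stigma
  need a modified occupancy model.
* No compensation by cheapening gametes (`r_f`, `r_m` changes) — out of
  scope, as is any physiological or evolutionary mechanism that would
  realize the parameter adjustments.
* `R`, `w`, `h` are treated as independent dials, though in the field all
  three co-vary with the same meteorology.
* Insect pollination is representable only indirectly (small effective `h`,
  small `w`); nothing here models pollinator behaviour.
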