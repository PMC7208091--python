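"""Resource-decline scenarios and the three compensation strategies."""

import numpy as np
import pytest

from conftest import random_paramsets
from sexalloc import (
    DeclineScenario,
    DispersalParams,
    ParameterError,
    ReproductionParams,
    ResourceBudget,
    apply_decline,
    compensable_by_allocation,
    compensate_range,
    compensate_retention,
    compensation_map,
    expected_fertilized,
    gamete_counts,
    optimal_allocation,
)

RETENTION_CASE = dict(R=5000, r_f=10, r_m=1, alpha=0.5, w=0.4, h=1000, q=0.9)


def make_scenario(R, r_f, r_m, alpha, w, h, q) -> DeclineScenario:
    return DeclineScenario(
        q=q, params=ReproductionParams(R, r_f, r_m, alpha), disp=DispersalParams(h=h, w=w)
    )


def random_scenarios(n, seed):
    rng = np.random.default_rng(seed)
    sets = random_paramsets(n, seed=seed + 1)
    return [
        DeclineScenario(q=float(rng.uniform(0.05, 1.0)), params=p, disp=d)
        for p, d in sets
    ]


class TestApplyDecline:
    def test_no_decline_is_identity(self):
        scen = make_scenario(**{**RETENTION_CASE, "q": 1.0})
        counts, stats = apply_decline(scen)
        assert counts == gamete_counts(scen.params)
        assert stats.E_Fstar == pytest.approx(scen.baseline.E_Fstar, rel=1e-12)

    def test_counts_scale_linearly(self):
        scen = make_scenario(R=5000, r_f=10, r_m=1, alpha=0.5, w=1, h=1000, q=0.5)
        counts, _ = apply_decline(scen)
        assert counts.F == pytest.approx(125)
        assert counts.M == pytest.approx(1250)
        # consistency with gamete production on the reduced budget
        assert counts == gamete_counts(scen.declined_params)

    def test_expectation_strictly_decreasing_in_decline(self):
        vals = []
        for q in np.linspace(1.0, 0.1, 10):
            scen = make_scenario(**{**RETENTION_CASE, "q": q})
            vals.append(apply_decline(scen)[1].E_Fstar)
        assert np.all(np.diff(vals) < 0)

    def test_invalid_q(self):
        with pytest.raises(ParameterError):
            make_scenario(**{**RETENTION_CASE, "q": 0.0})
        with pytest.raises(ParameterError):
            make_scenario(**{**RETENTION_CASE, "q": 1.2})


class TestAllocationStrategy:
    def test_baseline_at_optimum_leaves_no_headroom(self):
        budget = ResourceBudget(5000, 10, 1)
        disp = DispersalParams(h=1000, w=1)
        a_hat = optimal_allocation(budget, disp).alpha_hat
        scen = DeclineScenario(q=0.9, params=budget.with_allocation(a_hat), disp=disp)
        res = compensable_by_allocation(scen)
        assert not res.feasible
        assert res.infeasibility_reason == "exceeds_max_after_decline"

    def test_feasible_scenario_returns_dual_pair(self):
        """A suboptimal baseline (alpha=0.35) leaves headroom: after a 20%
        decline two allocations restore the baseline expectation exactly."""
        scen = make_scenario(R=5000, r_f=10, r_m=1, alpha=0.35, w=1, h=1000, q=0.8)
        # grid-search oracle confirms feasibility
        grid = np.linspace(0.01, 0.99, 2000)
        max_after = max(
            expected_fertilized(
                ReproductionParams(0.8 * 5000, 10, 1, a), scen.disp
            ).E_Fstar
            for a in grid
        )
        assert scen.baseline.E_Fstar <= max_after
        res = compensable_by_allocation(scen)
        assert res.feasible
        a1, a2 = res.adjusted_value
        assert a1 < res.alpha_hat_after < a2
        for a in (a1, a2):
            achieved = expected_fertilized(
                ReproductionParams(0.8 * 5000, 10, 1, a), scen.disp
            ).E_Fstar
            assert achieved == pytest.approx(scen.baseline.E_Fstar, rel=1e-8)

    def test_feasibility_boundary_against_grid_oracle(self):
        """Decreasing q flips the verdict exactly where the grid-search
        maximum under qR crosses the baseline expectation."""
        params = ReproductionParams(5000, 10, 1, 0.35)
        disp = DispersalParams(h=1000, w=1)
        base = expected_fertilized(params, disp).E_Fstar
        grid = np.linspace(0.01, 0.99, 4000)
        for q in np.linspace(0.95, 0.3, 14):
            scen = DeclineScenario(q=q, params=params, disp=disp)
            max_after = max(
                expected_fertilized(ReproductionParams(q * 5000, 10, 1, a), disp).E_Fstar
                for a in grid
            )
            verdict = compensable_by_allocation(scen).feasible
            if abs(max_after - base) > 1e-3 * base:  # away from the knife edge
                assert verdict == (base <= max_after)


class TestDensityStrategies:
    def test_retention_reference_case(self):
        scen = make_scenario(**RETENTION_CASE)
        assert scen.baseline.E_Fstar == pytest.approx(158.1, abs=0.1)
        res = compensate_retention(scen)
        assert res.feasible
        assert res.adjusted_value == pytest.approx(0.5386, abs=1e-3)
        assert res.achieved_E_Fstar == pytest.approx(scen.baseline.E_Fstar, rel=1e-8)
        # bisection oracle on the forward map w -> E(F*) under qR
        from scipy.optimize import brentq

        def gap(w):
            return (
                expected_fertilized(
                    scen.declined_params, DispersalParams(h=1000, w=w)
                ).E_Fstar
                - scen.baseline.E_Fstar
            )

        assert res.adjusted_value == pytest.approx(
            brentq(gap, 0.01, 1.0, xtol=1e-12), abs=1e-9
        )

    def test_range_reference_case(self):
        scen = make_scenario(**RETENTION_CASE)
        res = compensate_range(scen)
        assert res.feasible
        assert res.adjusted_value == pytest.approx(742.8, abs=0.5)
        assert res.adjusted_value >= 0.9 * 250  # h' >= qF
        assert res.achieved_E_Fstar == pytest.approx(scen.baseline.E_Fstar, rel=1e-8)
        from scipy.optimize import brentq

        def gap(h):
            return (
                expected_fertilized(
                    scen.declined_params, DispersalParams(h=h, w=0.4)
                ).E_Fstar
                - scen.baseline.E_Fstar
            )

        assert res.adjusted_value == pytest.approx(
            brentq(gap, 230, 1000, xtol=1e-9), abs=1e-6
        )

    def test_severe_decline_blocks_both(self):
        # E(P) = 0.632 at w=1; q below it fails the shared necessary condition
        scen = make_scenario(R=5000, r_f=10, r_m=1, alpha=0.5, w=1, h=1000, q=0.5)
        for fn in (compensate_retention, compensate_range):
            res = fn(scen)
            assert not res.feasible
            assert res.infeasibility_reason == "decline_too_severe"

    def test_retention_ceiling(self):
        # w=0.8: E(P)=0.865 < q=0.9, but the solved w' = 1.44 exceeds 1
        scen = make_scenario(R=5000, r_f=10, r_m=1, alpha=0.5, w=0.8, h=1000, q=0.9)
        res = compensate_retention(scen)
        assert not res.feasible
        assert res.infeasibility_reason == "retention_ceiling"

    def test_range_strategy_has_two_thresholds_on_h_grid(self):
        """Along a grid of baseline range sizes the verdict passes through the
        two regimes: q <= E(P) (range too small, decline too severe), then a
        solvable h' that is still below the qF ovules it must hold, and only
        above a second threshold does compensation become feasible."""
        reasons = []
        for h in np.linspace(260, 1000, 40):
            scen = make_scenario(R=5000, r_f=10, r_m=1, alpha=0.5, w=0.4, h=h, q=0.9)
            res = compensate_range(scen)
            reasons.append(res.infeasibility_reason)
        assert reasons[0] == "decline_too_severe"
        assert "range_below_ovule_count" in reasons
        assert reasons[-1] is None  # feasible for a large enough baseline range
        # regimes appear in order, each exactly once
        collapsed = [r for i, r in enumerate(reasons) if i == 0 or r != reasons[i - 1]]
        assert collapsed == ["decline_too_severe", "range_below_ovule_count", None]

    def test_feasible_compensations_restore_baseline_and_raise_density(self):
        n_checked = 0
        for scen in random_scenarios(60, seed=41):
            base = scen.baseline.E_Fstar
            ret = compensate_retention(scen)
            rng_ = compensate_range(scen)
            if ret.feasible:
                assert ret.achieved_E_Fstar == pytest.approx(base, rel=1e-8)
                assert ret.adjusted_value >= scen.disp.w - 1e-12  # density up
                n_checked += 1
            if rng_.feasible:
                assert rng_.achieved_E_Fstar == pytest.approx(base, rel=1e-8)
                assert rng_.adjusted_value <= scen.disp.h + 1e-9
            if scen.q <= scen.baseline.E_P:
                assert not ret.feasible and not rng_.feasible
        assert n_checked > 5

    def test_round_up_hands_integer_to_simulator(self):
        scen = make_scenario(**RETENTION_CASE)
        res = compensate_range(scen, round_up=True)
        assert res.adjusted_value == 743.0


class TestCompensationMap:
    GRID = dict(
        params=ReproductionParams(5000, 10, 1, 0.5),
        w_grid=np.linspace(0.1, 1.0, 8),
        h_grid=np.linspace(300, 3000, 8),
    )

    def test_no_decline_all_feasible(self):
        tab = compensation_map(q=1.0, **self.GRID)
        assert tab["retention_feasible"].all()
        assert tab["range_feasible"].all()
        # no adjustment needed: w' = w and h' = h
        assert np.allclose(tab["w_prime"], tab["w"])
        assert np.allclose(tab["h_prime"], tab["h"])

    def test_milder_decline_has_larger_feasible_region(self):
        mild = compensation_map(q=0.9, **self.GRID)
        severe = compensation_map(q=0.4, **self.GRID)
        for col in ("retention_feasible", "range_feasible"):
            assert severe[col].sum() < mild[col].sum()

    def test_monotone_severity(self):
        """Lowering q never turns an infeasible cell feasible."""
        prev = None
        for q in (1.0, 0.8, 0.6, 0.4):
            tab = compensation_map(q=q, **self.GRID)
            flags = tab[["retention_feasible", "range_feasible"]].to_numpy()
            if prev is not None:
                assert not np.any(flags & ~prev)
            prev = flags

    def test_shared_necessary_condition(self):
        tab = compensation_map(q=0.6, **self.GRID)
        blocked = tab["E_P"] >= 0.6
        assert blocked.any()
        assert not tab.loc[blocked, "retention_feasible"].any()
        assert not tab.loc[blocked, "range_feasible"].any()
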