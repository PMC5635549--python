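"""Cohort engine: CRN pairing, aggregation, sensitivity and threshold search."""

import numpy as np
import pytest

from prekcea.engine import (
    compare_arms,
    lifetable_for,
    one_way_sa,
    run_arm,
    threshold_search,
)
from prekcea.lifetables import LifeTable, life_expectancy
from prekcea.outcomes import program_cost_per_student
from prekcea.parameters import ScenarioConfig
from prekcea.risk_math import discount_factor

from conftest import null_intervention, zero_disease_registry


def zero_cost_config(**kwargs):
    """Scenario with no program outlay (capacity and implementation free)."""
    base = dict(capacity_cost=0.0, annual_implementation_cost=0.0)
    base.update(kwargs)
    return ScenarioConfig(**base)


class TestRunArm:
    def test_deterministic_degenerate_lifetime(self, registry):
        """No diseases, no background mortality until the terminal age:
        every life lasts exactly max_age - entry_age years."""
        qx = np.zeros(106)
        qx[105] = 1.0
        lt = LifeTable(qx=qx)
        cfg = ScenarioConfig(n_individuals=1, seed=0)
        res = run_arm(cfg, zero_disease_registry(registry), lt)
        assert res.mean_life_years == 105 - 5

    def test_zero_discount_full_health_qalys_equal_life_years(self, registry):
        qx = np.zeros(106)
        qx[105] = 1.0
        lt = LifeTable(qx=qx)
        cfg = ScenarioConfig(n_individuals=10, seed=0, discount_rate=0.0)
        res = run_arm(cfg, zero_disease_registry(registry), lt)
        assert res.mean_disc_qaly == pytest.approx(res.mean_life_years)

    def test_healthy_cohort_matches_life_table_expectation(self, registry,
                                                           lifetable):
        cfg = ScenarioConfig(n_individuals=50_000, seed=3)
        res = run_arm(cfg, zero_disease_registry(registry), lifetable)
        expected = 13 + life_expectancy(lifetable, 18)
        sd_bound = 15.0  # conservative upper bound on lifetime SD (years)
        assert abs(res.mean_life_years - expected) < 3 * sd_bound / np.sqrt(res.n)


class TestCompareArms:
    def test_null_intervention_crn_exact_zero(self, registry, lifetable):
        cfg = zero_cost_config(n_individuals=5_000, seed=21)
        res = compare_arms(cfg, null_intervention(registry), lifetable)
        assert res.delta_cost == 0.0
        assert res.delta_qaly == 0.0
        assert res.delta_life_years == 0.0

    def test_program_cost_only_delta(self, registry, lifetable):
        cfg = ScenarioConfig(n_individuals=2_000, seed=8)
        res = compare_arms(cfg, null_intervention(registry), lifetable)
        cps = program_cost_per_student(200_000, 5, 40_000, 72)
        assert res.delta_cost == pytest.approx(cps, rel=1e-9)
        assert res.delta_qaly == 0.0

    def test_base_case_direction_qaly(self, registry, lifetable):
        cfg = ScenarioConfig(n_individuals=30_000, seed=13)
        res = compare_arms(cfg, registry, lifetable)
        assert res.delta_qaly > 3 * res.se_delta_qaly

    def test_seed_reproducibility(self, registry, lifetable):
        cfg = ScenarioConfig(n_individuals=2_000, seed=17)
        a = compare_arms(cfg, registry, lifetable)
        b = compare_arms(cfg, registry, lifetable)
        assert a == b

    def test_results_independent_of_cohort_size_prefix(self, registry, lifetable):
        """Individual i's outcome must not depend on how many others run."""
        from prekcea.engine import _simulate_arm_arrays

        small = _simulate_arm_arrays(
            ScenarioConfig(n_individuals=500, seed=4), registry, lifetable,
            "standard", 4)
        large = _simulate_arm_arrays(
            ScenarioConfig(n_individuals=1_500, seed=4), registry, lifetable,
            "standard", 4)
        for key in small:
            assert np.array_equal(small[key], large[key][:500])

    def test_crn_variance_reduction(self, registry, lifetable):
        """Paired-arm SE under CRN is below the independent-stream SE."""
        cfg = ScenarioConfig(n_individuals=10_000, seed=31)
        crn = compare_arms(cfg, registry, lifetable)
        ind_std = run_arm(cfg.model_copy(update={"arm": "standard"}),
                          registry, lifetable, seed=31)
        ind_itv = run_arm(cfg.model_copy(update={"arm": "intervention"}),
                          registry, lifetable, seed=32)
        se_indep = np.hypot(ind_std.se_cost, ind_itv.se_cost)
        assert crn.se_delta_cost <= se_indep

    def test_se_scales_with_sqrt_n(self, registry, lifetable):
        res_small = compare_arms(
            ScenarioConfig(n_individuals=4_000, seed=9), registry, lifetable)
        res_big = compare_arms(
            ScenarioConfig(n_individuals=16_000, seed=9), registry, lifetable)
        ratio = res_small.se_delta_cost / res_big.se_delta_cost
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_qaly_bounded_by_discount_annuity(self, registry, lifetable):
        from prekcea.engine import _simulate_arm_arrays

        cfg = ScenarioConfig(n_individuals=2_000, seed=5)
        arrays = _simulate_arm_arrays(cfg, registry, lifetable, "standard", 5)
        d = discount_factor(cfg.discount_rate, np.arange(110))
        bounds = np.cumsum(d)[arrays["life_years"].astype(int) - 1]
        assert np.all(arrays["disc_qaly"] <= bounds + 1e-9)


class TestOneWaySA:
    def test_degenerate_range_gives_zero_spread(self, registry, lifetable):
        cfg = zero_cost_config(n_individuals=500, seed=2)
        with pytest.warns(UserWarning):
            entries = one_way_sa(cfg, registry, lifetable,
                                 params=["cost_obesity_treatment"])
        assert len(entries) == 1
        assert entries[0].spread == 0.0

    def test_cost_parameter_cannot_move_qalys(self, registry, lifetable):
        cfg = zero_cost_config(n_individuals=2_000, seed=2)
        entries = one_way_sa(cfg, registry, lifetable,
                             params=["cost_incarceration"],
                             outcome="delta_qaly")
        assert entries[0].spread == 0.0

    def test_widening_a_range_widens_or_preserves_the_bar(self, registry,
                                                          lifetable):
        from dataclasses import replace

        cfg = zero_cost_config(n_individuals=2_000, seed=2)
        name = "or_pc_behavior"
        narrow = one_way_sa(cfg, registry, lifetable, params=[name])[0]
        spec = registry[name]
        widened = registry.replace_spec(
            replace(spec, low=spec.low * 0.8, high=min(spec.high * 1.2, 1.0)))
        wide = one_way_sa(cfg, widened, lifetable, params=[name])[0]
        assert wide.spread >= narrow.spread - 1e-9

    def test_base_outcome_recorded(self, registry, lifetable):
        cfg = zero_cost_config(n_individuals=1_000, seed=2)
        entries = one_way_sa(cfg, registry, lifetable, params=["or_pc_behavior"])
        base = compare_arms(cfg, registry, lifetable).delta_cost
        assert entries[0].base_outcome == pytest.approx(base)


class TestThresholdSearch:
    def test_cost_per_student_threshold_equals_gross_savings(self, registry,
                                                             lifetable):
        """With the program cost as the free variable, the break-even price
        equals the gross per-person savings (an identity under CRN)."""
        cfg = ScenarioConfig(n_individuals=5_000, seed=12)
        gross = compare_arms(cfg, registry, lifetable,
                             cost_per_student=0.0).delta_cost
        thr = threshold_search(cfg, registry, lifetable,
                               param="cost_per_student", bracket=(0.0, 10_000.0))
        assert thr == pytest.approx(-gross, abs=10_000 * 1e-3)

    def test_null_effect_threshold_is_zero(self, registry, lifetable):
        cfg = zero_cost_config(n_individuals=2_000, seed=12)
        thr = threshold_search(cfg, null_intervention(registry), lifetable,
                               param="cost_per_student", bracket=(0.0, 10_000.0))
        assert thr == 0.0

    def test_school_size_matches_exhaustive_compare_scan(self, registry,
                                                         lifetable):
        cfg = ScenarioConfig(n_individuals=5_000, seed=12)
        thr = int(threshold_search(cfg, registry, lifetable,
                                   param="school_size", bracket=(1, 200)))
        # oracle: recompute full comparisons either side of the crossing
        def delta_at(s):
            cps = program_cost_per_student(
                cfg.capacity_cost, cfg.capacity_durability,
                cfg.annual_implementation_cost, s)
            return compare_arms(cfg, registry, lifetable,
                                cost_per_student=cps).delta_cost
        assert delta_at(thr) < 0
        assert delta_at(thr - 1) >= 0

    def test_bisection_matches_grid_scan(self, registry, lifetable):
        cfg = ScenarioConfig(n_individuals=5_000, seed=12)
        gross = compare_arms(cfg, registry, lifetable,
                             cost_per_student=0.0).delta_cost
        thr = threshold_search(cfg, registry, lifetable,
                               param="cost_per_student",
                               bracket=(0.0, 5_000.0), rel_tol=1e-4)
        grid = np.linspace(0.0, 5_000.0, 20_001)
        crossing = grid[np.searchsorted(gross + grid, 0.0)]
        assert thr == pytest.approx(crossing, abs=5_000 * 1e-3)

    def test_no_sign_change_reports_endpoints(self, registry, lifetable):
        cfg = zero_cost_config(n_individuals=1_000, seed=12)
        with pytest.raises(ValueError, match="sign"):
            threshold_search(cfg, registry, lifetable,
                             param="cost_per_student",
                             bracket=(5_000.0, 10_000.0))
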