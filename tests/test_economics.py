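"""Cost/effect accumulation, CPI adjustment, ICER and threshold logic."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dlbclcea.economics import (
    CostComponent,
    CPISeries,
    OutcomeSummary,
    StateCostProfile,
    StateCosts,
    UtilityProfile,
    accumulate_costs,
    accumulate_effects,
    compute_icer,
    cpi_adjust,
    gdp_threshold,
    summarize_arm,
)
from dlbclcea.model import CyclePlan, ModelConfig, build_transition_matrix, run_cohort

CYCLE_YEARS = CyclePlan().cycle_length_years


def flat_profile(arm="CHOP", dmc=368.5, drug=50.7, dnmc=86.8, ic=144.2):
    state = StateCosts(
        dmc=CostComponent(dmc),
        drug=CostComponent(drug),
        dnmc=CostComponent(dnmc),
        ic=CostComponent(ic),
    )
    return StateCostProfile(arm=arm, progression_free=state, progressive=state)


def stay_pf_trace(n_cycles):
    m = build_transition_matrix(0.0, 0.0, 0.0)
    return run_cohort(m, CyclePlan(max_cycles=n_cycles))


def all_dead_trace():
    m = build_transition_matrix(0.0, 1.0, 1.0)
    return run_cohort(m, CyclePlan(max_cycles=10))


class TestCPI:
    series = CPISeries({2015: 100.0, 2016: 103.0, 2019: 114.0})

    def test_same_year_identity(self):
        assert cpi_adjust(100.0, 2019, 2019, self.series) == 100.0

    def test_ratio_arithmetic(self):
        assert cpi_adjust(100.0, 2015, 2019, self.series) == pytest.approx(114.0)

    def test_zero_cost_stays_zero(self):
        assert cpi_adjust(0.0, 2016, 2019, self.series) == 0.0

    def test_missing_year_named_in_error(self):
        with pytest.raises(KeyError, match="2017"):
            cpi_adjust(10.0, 2017, 2019, self.series)

    def test_non_positive_index_rejected(self):
        with pytest.raises(ValueError):
            CPISeries({2019: 0.0})


class TestAccumulateCosts:
    def test_single_cycle_sums_components(self, no_discount_config, plan):
        trace = stay_pf_trace(1)
        disc, undisc, comps = accumulate_costs(
            trace, flat_profile(), no_discount_config, plan, treatment_cycle_cap=None
        )
        assert disc == pytest.approx(650.2)
        assert undisc == pytest.approx(650.2)
        assert comps["drug"] == pytest.approx(50.7)

    def test_death_costs_nothing(self, config, plan):
        trace = all_dead_trace()
        disc, undisc, _ = accumulate_costs(trace, flat_profile(), config, plan)
        # only the first (half) cycle contributes while the cohort dies
        assert undisc <= 650.2
        trace2 = stay_pf_trace(1)
        # sanity: full-death occupancy rows contribute zero
        assert disc < accumulate_costs(trace2, flat_profile(), config, plan)[0] + 650.2

    def test_two_cycle_discounting_at_cycle_start(self, plan):
        cfg = ModelConfig(half_cycle_correction=False)
        trace = stay_pf_trace(2)
        profile = flat_profile(dmc=100.0, drug=0.0, dnmc=0.0, ic=0.0)
        disc, undisc, _ = accumulate_costs(trace, profile, cfg, plan)
        assert disc == pytest.approx(199.830196, abs=1e-5)
        assert undisc == pytest.approx(200.0)

    def test_treatment_cap_restricts_only_drug_component(self, no_discount_config, plan):
        trace = stay_pf_trace(10)
        disc, _, comps = accumulate_costs(
            trace, flat_profile(), no_discount_config, plan, treatment_cycle_cap=8
        )
        assert comps["drug"] == pytest.approx(8 * 50.7)
        assert comps["dmc"] == pytest.approx(10 * 368.5)
        assert disc == pytest.approx(8 * 50.7 + 10 * (368.5 + 86.8 + 144.2))

    def test_discounted_never_exceeds_undiscounted(self, config, plan):
        trace = stay_pf_trace(50)
        disc, undisc, _ = accumulate_costs(trace, flat_profile(), config, plan)
        assert disc < undisc


class TestAccumulateEffects:
    def test_single_cycle_life_year_and_qaly(self, no_discount_config, plan):
        trace = stay_pf_trace(1)
        ly, qaly, ly_u, qaly_u = accumulate_effects(
            trace, UtilityProfile(), no_discount_config, plan
        )
        assert ly == pytest.approx(CYCLE_YEARS, abs=1e-12)
        assert qaly == pytest.approx(0.74 * CYCLE_YEARS, abs=1e-12)

    def test_perfect_health_equates_qalys_and_life_years(self, config, plan):
        trace = stay_pf_trace(20)
        utilities = UtilityProfile(progression_free=1.0, progressive=1.0)
        ly, qaly, ly_u, qaly_u = accumulate_effects(trace, utilities, config, plan)
        assert qaly == pytest.approx(ly, abs=1e-12)
        assert qaly_u == pytest.approx(ly_u, abs=1e-12)

    def test_dead_cohort_accrues_nothing(self, config, plan):
        m = build_transition_matrix(0.0, 1.0, 1.0)
        trace = run_cohort(m, CyclePlan(max_cycles=10))
        cfg = ModelConfig(half_cycle_correction=False)
        ly, qaly, *_ = accumulate_effects(trace, UtilityProfile(), cfg, plan)
        # only the first cycle (cohort alive at its start) contributes
        assert ly == pytest.approx(CYCLE_YEARS)
        # after absorption: zero
        trace_tail = np.array([0.0, 0.0, 1.0])
        assert (trace.occupancy[1:] @ UtilityProfile().as_array()).sum() == 0.0

    def test_qaly_never_exceeds_life_years(self, config, plan):
        m = build_transition_matrix(0.1, 0.01, 0.2)
        trace = run_cohort(m, CyclePlan(max_cycles=200))
        ly, qaly, ly_u, qaly_u = accumulate_effects(
            trace, UtilityProfile(), config, plan
        )
        assert qaly < ly
        assert qaly_u < ly_u


def summary(arm, cost, qaly, ly=None):
    ly = qaly if ly is None else ly
    return OutcomeSummary(
        arm=arm,
        total_cost=cost,
        life_years=ly,
        qalys=qaly,
        total_cost_undiscounted=cost,
        life_years_undiscounted=ly,
        qalys_undiscounted=qaly,
    )


class TestComputeICER:
    def test_published_style_ratio(self):
        res = compute_icer(
            summary("R-CHOP", 105847.0, 4.18), summary("CHOP", 94931.0, 3.00),
            "QALY", 11538.0,
        )
        assert res.icer == pytest.approx(10916.0 / 1.18, rel=1e-9)
        assert res.cost_effective  # 9251 < 11538

    def test_cheaper_and_better_is_dominant(self):
        res = compute_icer(summary("A", 99.0, 2.0), summary("B", 100.0, 1.0))
        assert res.label == "dominant" and res.icer is None
        assert res.cost_effective

    def test_free_benefit_has_zero_icer(self):
        res = compute_icer(summary("A", 100.0, 2.0), summary("B", 100.0, 1.0))
        assert res.icer == 0.0
        assert res.cost_effective

    def test_equal_effects_never_divide(self):
        res = compute_icer(summary("A", 120.0, 1.0), summary("B", 100.0, 1.0))
        assert res.icer is None and res.label == "dominated"
        res2 = compute_icer(summary("A", 100.0, 1.0), summary("B", 100.0, 1.0))
        assert res2.label == "equivalent"

    def test_order_reversal_flips_consistently(self):
        a, b = summary("A", 120.0, 2.0), summary("B", 100.0, 1.0)
        fwd = compute_icer(a, b)
        rev = compute_icer(b, a)
        assert fwd.icer == pytest.approx(abs(rev.icer))
        assert rev.delta_cost == -fwd.delta_cost
        assert not rev.cost_effective  # losing a QALY to save money is not CE here

    def test_dominance_inverts_on_reversal(self):
        a, b = summary("A", 99.0, 2.0), summary("B", 100.0, 1.0)
        assert compute_icer(a, b).label == "dominant"
        assert compute_icer(b, a).label == "dominated"


class TestGDPThreshold:
    @pytest.mark.parametrize("mult, expected", [(1, 3846.0), (2, 7692.0), (3, 11538.0)])
    def test_gdp_multiples_exact(self, mult, expected):
        assert gdp_threshold(3846.0, mult) == expected

    def test_identity_multiplier(self):
        assert gdp_threshold(5000.0, 1) == 5000.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gdp_threshold(-1.0, 1)
        with pytest.raises(ValueError):
            gdp_threshold(3846.0, 4)


class TestScalingInvariants:
    def _summaries(self, scale=1.0):
        plan = CyclePlan(max_cycles=120)
        cfg = ModelConfig()
        m_a = build_transition_matrix(0.02, 0.004, 0.05)
        m_b = build_transition_matrix(0.05, 0.004, 0.08)
        util = UtilityProfile()
        out = []
        for arm, m in (("A", m_a), ("B", m_b)):
            trace = run_cohort(m, plan)
            prof = flat_profile(
                arm, dmc=368.5 * scale, drug=50.7 * scale, dnmc=86.8 * scale,
                ic=144.2 * scale,
            )
            out.append(summarize_arm(trace, prof, util, cfg, plan))
        return out

    def test_cost_scaling_scales_icer_exactly(self):
        a1, b1 = self._summaries(1.0)
        a2, b2 = self._summaries(2.5)
        r1 = compute_icer(a1, b1)
        r2 = compute_icer(a2, b2)
        assert r2.delta_cost == pytest.approx(2.5 * r1.delta_cost, rel=1e-12)
        assert r2.icer == pytest.approx(2.5 * r1.icer, rel=1e-12)
        assert r2.delta_effect == pytest.approx(r1.delta_effect, rel=1e-12)

    def test_identical_traces_never_yield_numeric_positive_icer(self, config, plan):
        m = build_transition_matrix(0.05, 0.004, 0.08)
        trace = run_cohort(m, CyclePlan(max_cycles=120))
        util = UtilityProfile()
        pln = CyclePlan(max_cycles=120)
        s_a = summarize_arm(trace, flat_profile("A"), util, config, pln)
        s_b = summarize_arm(trace, flat_profile("B"), util, config, pln)
        res = compute_icer(s_a, s_b)
        assert res.icer is None
        assert res.label in {"equivalent", "dominant", "dominated"}


def test_negative_cost_inputs_rejected():
    with pytest.raises(ValueError):
        CostComponent(-1.0)
    with pytest.raises(ValueError):
        CostComponent(10.0, -1.0)


def test_utility_bounds_enforced():
    with pytest.raises(ValueError):
        UtilityProfile(progression_free=1.5)
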