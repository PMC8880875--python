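"""Markov engine: discounting, mortality, cost accrual, cohort traces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mdma_cea as m
from mdma_cea.engine import savings_delta


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "t, r, expected",
        [(1, 0.0, 1.0), (1, 0.03, 0.970874), (30, 0.03, 0.411987)],
    )
    def test_closed_form(self, t, r, expected):
        assert m.discount_factor(t, r) == pytest.approx(expected, abs=5e-7)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            m.discount_factor(1, -0.01)
        with pytest.raises(ValueError):
            m.discount_factor(0, 0.03)

    def test_strictly_decreasing_for_positive_rate(self):
        f = [m.discount_factor(t, 0.03) for t in range(1, 31)]
        assert all(a > b for a, b in zip(f, f[1:]))


class TestDeathProbability:
    def test_reference_age_by_state(self, base):
        lt = base.life_table
        assert m.death_probability("asymptomatic", 41, base.rr, lt) == pytest.approx(0.0020)
        assert m.death_probability("severe", 41, base.rr, lt) == pytest.approx(0.00502)

    def test_probability_is_capped_at_one(self, base):
        lt = m.LifeTable(ages=np.arange(0, 121.0), qx=np.full(121, 0.5))
        assert m.death_probability("extreme", 41, base.rr, lt) == 1.0


class TestAnnualMedicalCost:
    def test_control_intake_mix(self, base):
        cost = m.annual_medical_cost(
            m.control_arm(base), 1, base, m.SeverityDistribution([0, 0, 0, 714, 286])
        )
        assert cost == pytest.approx(714 * 20_236 + 286 * 24_283)  # 21,393,442

    def test_mdma_year_one_pays_full_intake_mix_cost(self, base):
        """No savings are released in the first year after therapy."""
        occupancy = m.SeverityDistribution(base.followup.counts)
        cost = m.annual_medical_cost(m.mdma_arm(base), 1, base, occupancy)
        assert cost == pytest.approx(base.intake.per_capita(base.costs.mean) * 1000)

    def test_mdma_full_ramp_pays_followup_mix_cost(self, base):
        occupancy = m.SeverityDistribution(base.followup.counts)
        cost = m.annual_medical_cost(m.mdma_arm(base), 5, base, occupancy)
        assert cost == pytest.approx(base.followup.per_capita(base.costs.mean) * 1000)

    def test_cycle_index_must_be_positive(self, base):
        with pytest.raises(ValueError):
            m.annual_medical_cost(m.control_arm(base), 0, base, base.intake)


class TestApplyProgression:
    def test_single_state_shift(self):
        out = m.apply_progression(np.array([100.0, 0, 0, 0, 0]), 0.10)
        np.testing.assert_allclose(out, [90, 10, 0, 0, 0])

    def test_most_severe_state_retains_mass(self):
        out = m.apply_progression(np.array([0.0, 0, 0, 0, 100]), 0.20)
        np.testing.assert_allclose(out, [0, 0, 0, 0, 100])

    def test_published_followup_mix_mass_balance(self):
        start = np.array([333.0, 262, 262, 119, 24])
        out = m.apply_progression(start, 0.10)
        # mass-balance oracle: each state keeps 90% and inherits 10% of its
        # less severe neighbour
        expected = [333 * 0.9, 262 * 0.9 + 33.3, 262 * 0.9 + 26.2, 119 * 0.9 + 26.2, 24 + 11.9]
        np.testing.assert_allclose(out, expected)
        assert out.sum() == pytest.approx(1000)

    @given(
        counts=st.lists(st.floats(0, 1e6), min_size=5, max_size=5),
        rate=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_conserved_for_any_rate(self, counts, rate):
        arr = np.array(counts)
        out = m.apply_progression(arr, rate)
        assert out.sum() == pytest.approx(arr.sum(), rel=1e-12, abs=1e-9)
        assert np.all(out >= 0)

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            m.apply_progression(np.ones(5), 1.5)


class TestRunCohort:
    def test_healthy_cohort_accrues_utility_weighted_years(self, flat_mortality_params):
        """1000 asymptomatic people, no deaths, no discounting -> 900 QALYs."""
        p = flat_mortality_params.replace(discount_rate=0.0)
        arm = m.ArmSpec("mdma", m.SeverityDistribution([1000, 0, 0, 0, 0]), True)
        trace = m.run_cohort(p, arm, horizon=1)
        assert trace.total_qalys() == pytest.approx(900.0, rel=1e-9)
        assert trace.total_deaths() == pytest.approx(0.0, abs=1e-6)
        assert trace.intervention_cost == pytest.approx(11_537_000)

    def test_control_utility_mass_matches_intake_mix(self, flat_mortality_params):
        """Before mortality, the standard-care arm holds 541.36 QALYs/year."""
        p = flat_mortality_params.replace(discount_rate=0.0)
        trace = m.run_cohort(p, m.control_arm(p), horizon=1)
        assert trace.total_qalys() == pytest.approx(714 * 0.61 + 286 * 0.37, rel=1e-9)

    def test_two_cycle_closed_form_oracle(self, base):
        """A scalar, hand-written reimplementation of two cycles agrees exactly.

        Single age stratum at 41; treated arm; default inputs.  The oracle
        uses plain python arithmetic and the Gompertz formula directly.
        """
        p = base.replace(age_sd=0.0)
        trace = m.run_cohort(p, m.mdma_arm(p), horizon=2)

        a = -math.log(1 - 0.0020)
        qx = [1 - math.exp(-a * math.exp(0.085 * (age - 41))) for age in (41, 42)]
        rr = [1.00, 1.74, 2.05, 2.51, 2.76]
        util = [0.90, 0.83, 0.74, 0.61, 0.37]
        cost = [5_032, 10_118, 15_177, 20_236, 24_283]
        occ = [333.0, 262.0, 262.0, 119.0, 24.0]
        pc_intake = (714 * cost[3] + 286 * cost[4]) / 1000
        pc_follow = sum(o * c for o, c in zip(occ, cost)) / 1000
        delta = pc_intake - pc_follow
        exp_q, exp_c, exp_d = [], [], []
        for t in (1, 2):
            surv = [o * (1 - min(1.0, r * qx[t - 1])) for o, r in zip(occ, rr)]
            disc = 1.03 ** -t
            exp_d.append(sum(occ) - sum(surv))
            exp_q.append(sum(s * u for s, u in zip(surv, util)) * disc)
            ramp = 0.25 * (t - 1)
            exp_c.append(
                (sum(s * c for s, c in zip(surv, cost)) + sum(surv) * (1 - ramp) * delta) * disc
            )
            occ = surv

        np.testing.assert_allclose(trace.qalys_disc, exp_q, rtol=1e-12)
        np.testing.assert_allclose(trace.med_cost_disc, exp_c, rtol=1e-12)
        np.testing.assert_allclose(trace.deaths, exp_d, rtol=1e-12)

    def test_mass_conservation_across_random_configs(self):
        for seed in range(8):
            p = m.random_config(seed)
            for arm in (m.mdma_arm(p), m.control_arm(p)):
                trace = m.run_cohort(p, arm)  # run_cohort asserts conservation
                living = trace.occupancy.sum(axis=1)
                cum_dead = np.cumsum(trace.deaths)
                np.testing.assert_allclose(living + cum_dead, p.cohort_size, rtol=1e-9)

    def test_zero_discount_totals_equal_undiscounted_sums(self, base):
        p = base.replace(discount_rate=0.0)
        trace = m.run_cohort(p, m.control_arm(p), horizon=10)
        # recompute undiscounted QALYs/costs from the occupancy record
        qalys = sum(trace.occupancy[t] @ p.utilities.values for t in range(10))
        costs = sum(trace.occupancy[t] @ p.costs.mean for t in range(10))
        assert trace.total_qalys() == pytest.approx(qalys, rel=1e-12)
        assert trace.total_cost() == pytest.approx(costs, rel=1e-12)

    def test_raising_mortality_rr_hurts_qalys_and_adds_deaths(self, base):
        worse_rr = base.rr.mean.copy()
        worse_rr[3] *= 1.5
        worse = base.replace(rr=m.MortalityRR(mean=worse_rr, sd=base.rr.sd))
        for params_pair in [(base, worse)]:
            t0 = m.run_cohort(params_pair[0], m.control_arm(params_pair[0]))
            t1 = m.run_cohort(params_pair[1], m.control_arm(params_pair[1]))
            assert t1.total_qalys() < t0.total_qalys()
            assert t1.total_deaths() > t0.total_deaths()

    def test_arm_symmetry_when_therapy_has_no_effect(self, base):
        """Follow-up mix == intake mix -> arms differ only by the intervention cost."""
        p = base.replace(followup=m.SeverityDistribution(base.intake.counts))
        tm = m.run_cohort(p, m.mdma_arm(p))
        tc = m.run_cohort(p, m.control_arm(p))
        res = m.compare_arms(tm, tc)
        assert res.net_cost == pytest.approx(11_537_000, rel=1e-12)
        assert res.qalys_gained == pytest.approx(0.0, abs=1e-9)
        assert res.deaths_averted == pytest.approx(0.0, abs=1e-9)

    def test_age_spread_raises_year_one_deaths(self, base):
        """qx is convex in age, so age heterogeneity adds year-1 mortality."""
        spread = m.run_cohort(base, m.control_arm(base), horizon=1)
        flat = m.run_cohort(base.replace(age_sd=0.0), m.control_arm(base), horizon=1)
        assert spread.total_deaths() > flat.total_deaths()

    def test_entrant_accrual_credits_more_than_survivor_accrual(self, base):
        surv = m.run_cohort(base, m.control_arm(base), accrual="survivor")
        entr = m.run_cohort(base, m.control_arm(base), accrual="entrant")
        assert entr.total_qalys() > surv.total_qalys()
        assert entr.total_cost() > surv.total_cost()
        np.testing.assert_allclose(entr.deaths, surv.deaths)  # mortality unchanged

    def test_domain_errors(self, base):
        with pytest.raises(ValueError):
            m.run_cohort(base, m.control_arm(base), horizon=0)
        with pytest.raises(ValueError):
            m.run_cohort(base, m.control_arm(base), accrual="midpoint")

    def test_trace_frame_is_tidy(self, base):
        trace = m.run_cohort(base, m.control_arm(base), horizon=3)
        df = trace.to_frame()
        assert len(df) == 3 * 5
        assert set(df.columns) >= {"cycle", "state", "occupancy", "deaths"}
        assert df.groupby("cycle")["deaths"].sum().tolist() == pytest.approx(
            trace.deaths.tolist()
        )
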