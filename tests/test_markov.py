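"""Markov engine: mortality combination, matrix structure, accrual identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eipcea.markov import (
    HealthState,
    LifeTable,
    N_STATES,
    StateValues,
    StrategySpec,
    TransitionParameters,
    build_transition_matrix,
    combine_mortality,
    remission_at_1yr,
    run_cohort,
)

S = HealthState
EIP = StrategySpec("EIP")
CAPS = StrategySpec("CAPS")


def flat_life_table(q=0.0, age_min=16, age_max=120):
    ages = np.arange(age_min, age_max + 1)
    return LifeTable(ages=ages, q=np.full(len(ages), q))


def unit_values(costs=None):
    u = np.array([1, 1, 1, 1, 1, 0], float)
    c = np.zeros(N_STATES) if costs is None else np.asarray(costs, float)
    return StateValues(annual_costs=c, utilities=u)


BASE = dict(
    p_fep_remission=0.48,
    p_fep_trs=0.10,
    p_fep_pns=0.07,
    p_remission_relapse=0.35,
    p_relapse_remission=0.40,
    p_relapse_trs=0.15,
    p_relapse_inpatient=0.30,
)


class TestCombineMortality:
    def test_identity_and_zero(self):
        assert combine_mortality(0.01, 1.0) == pytest.approx(0.01)
        assert combine_mortality(0.0, 7.3) == 0.0

    def test_closed_form_matches_rate_conversion(self):
        got = combine_mortality(0.01, 2.5)
        assert got == pytest.approx(0.024814, abs=1e-5)
        assert got == pytest.approx(1 - np.exp(2.5 * np.log(0.99)), abs=1e-12)

    def test_rejects_certain_death(self):
        with pytest.raises(ValueError):
            combine_mortality(1.0, 2.0)


class TestTransitionMatrix:
    def test_no_transitions_no_death_is_identity(self):
        p = TransitionParameters(
            p_fep_remission=0, p_fep_trs=0, p_fep_pns=0,
            p_remission_relapse=0, p_relapse_remission=0, p_relapse_trs=0,
            p_relapse_inpatient=0,
        )
        m = build_transition_matrix(p, CAPS, flat_life_table(0.0), 30, 0)
        assert np.array_equal(m, np.eye(N_STATES))

    def test_null_risk_ratios_make_strategies_identical(self):
        p = TransitionParameters(**BASE, rr_remission=1.0, rr_relapse=1.0, smr=2.5)
        lt = flat_life_table(0.01)
        for cyc in range(6):
            me = build_transition_matrix(p, EIP, lt, 26 + cyc, cyc)
            mc = build_transition_matrix(p, CAPS, lt, 26 + cyc, cyc)
            assert np.array_equal(me, mc)

    def test_eip_scales_remission_probability_within_effect_window(self):
        p = TransitionParameters(**BASE, rr_remission=1.22, rr_relapse=0.31, smr=2.5)
        lt = flat_life_table(0.002)
        m = build_transition_matrix(p, EIP, lt, 26, 0)
        d = m[S.FEP, S.DEATH]
        # conditional-on-survival probability is the scaled product
        assert m[S.FEP, S.REMISSION] / (1 - d) == pytest.approx(0.48 * 1.22)
        # beyond the 3-year package EIP reverts to CAPS dynamics
        m_late = build_transition_matrix(p, EIP, lt, 29, 3)
        assert m_late[S.FEP, S.REMISSION] / (1 - m_late[S.FEP, S.DEATH]) == pytest.approx(0.48)

    def test_scaled_probability_is_capped_to_keep_row_valid(self):
        p = TransitionParameters(**{**BASE, "p_fep_remission": 0.8}, rr_remission=2.0)
        m = build_transition_matrix(p, EIP, flat_life_table(0.0), 26, 0)
        assert m[S.FEP].sum() == pytest.approx(1.0)
        assert m[S.FEP, S.REMISSION] == pytest.approx(1.0 - 0.10 - 0.07)

    def test_inconsistent_parameters_raise(self):
        with pytest.raises(ValueError, match="residual stay-probability"):
            TransitionParameters(**{**BASE, "p_fep_remission": 0.9, "p_fep_trs": 0.2})

    @given(
        probs=st.lists(st.floats(0, 1), min_size=7, max_size=7),
        q=st.floats(0, 0.5),
        smr=st.floats(0.5, 6),
        rr_rem=st.floats(0.2, 3),
        rr_rel=st.floats(0.1, 2),
        cyc=st.integers(0, 9),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rows_always_sum_to_one(self, probs, q, smr, rr_rem, rr_rel, cyc):
        a, b, c, d_, e, f, g = probs
        total_fep = a + b + c or 1.0
        total_rel = d_ + e or 1.0
        p = TransitionParameters(
            p_fep_remission=a / max(total_fep, 1.0),
            p_fep_trs=b / max(total_fep, 1.0),
            p_fep_pns=c / max(total_fep, 1.0),
            p_remission_relapse=g,
            p_relapse_remission=d_ / max(total_rel, 1.0),
            p_relapse_trs=e / max(total_rel, 1.0),
            p_relapse_inpatient=f,
            rr_remission=rr_rem, rr_relapse=rr_rel, smr=smr,
        )
        m = build_transition_matrix(p, EIP, flat_life_table(q), 30, cyc)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m >= 0)


class TestRunCohort:
    def test_trace_starts_all_fep_and_conserves_mass(self, table, life_table):
        p = TransitionParameters.from_table(table)
        v = StateValues.from_table(table)
        res = run_cohort(p, v, EIP, life_table)
        occ = res.trace.occupancy
        assert occ[0, S.FEP] == 1.0 and occ[0].sum() == 1.0
        assert np.abs(occ.sum(axis=1) - 1.0).max() < 1e-9
        assert np.all(np.diff(occ[:, S.DEATH]) >= 0)

    def test_annuity_closed_form_for_static_alive_cohort(self):
        p = TransitionParameters(
            p_fep_remission=0, p_fep_trs=0, p_fep_pns=0,
            p_remission_relapse=0, p_relapse_remission=0, p_relapse_trs=0,
            p_relapse_inpatient=0,
        )
        res = run_cohort(p, unit_values(), CAPS, flat_life_table(0.0),
                         horizon=10, discount_rate=0.03)
        annuity = (1 - 1.03 ** -10) / 0.03
        assert res.discounted_qalys == pytest.approx(annuity, abs=1e-9)

    def test_zero_rate_discounting_is_identity(self, table, life_table):
        p = TransitionParameters.from_table(table)
        v = StateValues.from_table(table)
        res = run_cohort(p, v, EIP, life_table, discount_rate=0.0)
        assert res.discounted_cost == pytest.approx(res.cycle_costs.sum())
        assert res.discounted_qalys == pytest.approx(res.cycle_qalys.sum())

    def test_discounting_matches_brute_force_accumulator(self, table, life_table):
        p = TransitionParameters.from_table(table)
        v = StateValues.from_table(table)
        r = 0.07
        res = run_cohort(p, v, EIP, life_table, discount_rate=r, horizon=12)
        brute_c = sum(res.cycle_costs[t] * (1 + r) ** -t for t in range(13))
        brute_q = sum(res.cycle_qalys[t] * (1 + r) ** -t for t in range(13))
        assert res.discounted_cost == pytest.approx(brute_c, rel=1e-12)
        assert res.discounted_qalys == pytest.approx(brute_q, rel=1e-12)

    def test_qalys_nondecreasing_in_horizon(self, table, life_table):
        p = TransitionParameters.from_table(table)
        v = StateValues.from_table(table)
        q = [
            run_cohort(p, v, EIP, life_table, horizon=h).discounted_qalys
            for h in (5, 10, 20, 40)
        ]
        assert all(b >= a for a, b in zip(q, q[1:]))

    def test_smr_accelerates_death_occupancy(self, table, life_table):
        import dataclasses

        p = TransitionParameters.from_table(table)
        p1 = dataclasses.replace(p, smr=1.0)
        v = StateValues.from_table(table)
        occ_smr = run_cohort(p, v, CAPS, life_table).trace.occupancy
        occ_gen = run_cohort(p1, v, CAPS, life_table).trace.occupancy
        assert np.all(occ_smr[:, S.DEATH] >= occ_gen[:, S.DEATH] - 1e-15)

    def test_effective_eip_gains_qalys(self, table, life_table):
        """rr_remission > 1 and rr_relapse < 1 must yield positive ΔQALYs."""
        p = TransitionParameters.from_table(table)
        v = StateValues.from_table(table)
        res_e = run_cohort(p, v, EIP, life_table)
        res_c = run_cohort(p, v, CAPS, life_table)
        assert res_e.discounted_qalys > res_c.discounted_qalys

    def test_uncovered_life_table_raises(self, table):
        p = TransitionParameters.from_table(table)
        v = StateValues.from_table(table)
        with pytest.raises(ValueError, match="life table"):
            run_cohort(p, v, EIP, flat_life_table(0.001, 16, 30), horizon=10, start_age=26)


class TestRemissionAtOneYear:
    def test_identity_dynamics_give_zero(self):
        p = TransitionParameters(
            p_fep_remission=0, p_fep_trs=0, p_fep_pns=0,
            p_remission_relapse=0, p_relapse_remission=0, p_relapse_trs=0,
            p_relapse_inpatient=0,
        )
        res = run_cohort(p, unit_values(), CAPS, flat_life_table(0.0))
        assert remission_at_1yr(res.trace) == 0.0

    def test_matches_hand_multiplied_first_step(self, table, life_table):
        p = TransitionParameters.from_table(table)
        v = StateValues.from_table(table)
        res = run_cohort(p, v, EIP, life_table)
        m1 = build_transition_matrix(p, EIP, life_table, 26, 0)
        row0 = np.zeros(N_STATES)
        row0[S.FEP] = 1.0
        assert remission_at_1yr(res.trace) == pytest.approx((row0 @ m1)[S.REMISSION])

    def test_fixture_eip_remission_near_published_level(self, table, life_table):
        """Modelled 1-year EIP remission sits near 58.6 %."""
        p = TransitionParameters.from_table(table)
        v = StateValues.from_table(table)
        res = run_cohort(p, v, EIP, life_table)
        assert remission_at_1yr(res.trace) == pytest.approx(0.586, abs=0.01)
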