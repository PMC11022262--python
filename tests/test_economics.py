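"""Decision layer: ICER/NMB algebra, PSA, quadrants, CEAC, scenarios, currency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eipcea.economics import (
    CEACCurve,
    CurrencyConfig,
    ModelContext,
    PSASamples,
    ceac,
    compute_icer,
    compute_nmb,
    convert_currency,
    default_lambda_grid,
    icer_per_remission,
    incremental_nmb,
    quadrant_fractions,
    run_base_case,
    run_psa,
    run_scenarios,
)


def make_samples(d_cost, d_qalys):
    d_cost = np.asarray(d_cost, float)
    d_qalys = np.asarray(d_qalys, float)
    zero = np.zeros_like(d_cost)
    return PSASamples(
        parameters=pd.DataFrame(index=range(len(d_cost))),
        cost_eip=d_cost, qalys_eip=d_qalys, cost_caps=zero, qalys_caps=zero,
        seed=0,
    )


class TestIcerAndNmb:
    def test_direct_division_of_published_components(self):
        cea = compute_icer(0, 0, 4_478.0, 0.29)
        assert cea.icer == pytest.approx(4_478 / 0.29)  # 15,441 R$/QALY
        assert cea.icer_label == ""

    @pytest.mark.parametrize(
        "d_c, d_e, label",
        [(-1.0, 0.1, "EIP dominant"), (1.0, -0.1, "EIP dominated")],
    )
    def test_dominance_labels(self, d_c, d_e, label):
        assert compute_icer(0, 0, d_c, d_e).icer_label == label

    def test_zero_delta_qalys_is_undefined_without_division(self):
        cea = compute_icer(100, 1.0, 200, 1.0)
        assert cea.icer_label == "undefined"
        assert np.isnan(cea.icer)

    def test_zero_delta_cost_gives_zero_icer(self):
        assert compute_icer(0, 0, 0.0, 0.5).icer == 0.0

    def test_nmb_identities(self):
        assert compute_nmb(0.0, 5.0, 123.0) == -123.0
        inmb = incremental_nmb(18_254.0, 0.29, 4_478.0)
        assert inmb == pytest.approx(815.66, abs=0.01)
        lam_star = 4_478.0 / 0.29
        assert incremental_nmb(lam_star, 0.29, 4_478.0) == pytest.approx(0.0, abs=1e-9)

    @given(
        d_c=st.floats(-1e5, 1e5),
        d_e=st.floats(1e-4, 10),
        lam=st.floats(0, 1e6),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_decision_rule_consistency(self, d_c, d_e, lam):
        """For ΔE > 0: ICER < λ iff incremental NMB > 0."""
        icer = d_c / d_e
        inmb = incremental_nmb(lam, d_e, d_c)
        if icer < lam:
            assert inmb > 0 or np.isclose(inmb, 0)
        if inmb > 0 and not np.isclose(inmb, 0):
            assert icer < lam


class TestQuadrantsAndCeac:
    def test_all_dominant_draws_land_southeast(self):
        q = quadrant_fractions(make_samples([-1, -2, -3], [0.1, 0.2, 0.3]))
        assert q == {"NE": 0.0, "SE": 1.0, "SW": 0.0, "NW": 0.0}

    def test_symmetric_cloud_splits_evenly(self):
        rng = np.random.default_rng(0)
        n = 40_000
        q = quadrant_fractions(make_samples(rng.normal(size=n), rng.normal(size=n)))
        for frac in q.values():
            assert frac == pytest.approx(0.25, abs=3 * np.sqrt(0.25 * 0.75 / n))

    def test_fractions_sum_to_one_exactly_with_ties(self):
        q = quadrant_fractions(make_samples([0.0, 1.0, -1.0], [0.0, 1.0, -1.0]))
        assert sum(q.values()) == 1.0
        assert q["NE"] == pytest.approx(2 / 3)  # zeros on the positive side

    def test_ceac_definitional_limits(self):
        d_c = np.array([-1.0, 2.0, 3.0, -4.0])
        d_e = np.array([0.5, -0.5, 1.0, 1.0])
        curve = ceac(make_samples(d_c, d_e), [0.0, 1e9])
        assert curve.probability[0] == np.mean(d_c < 0)
        assert curve.probability[-1] == np.mean(d_e > 0)

    def test_ceac_rejects_bad_grid(self):
        s = make_samples([1.0], [1.0])
        with pytest.raises(ValueError):
            ceac(s, [])
        with pytest.raises(ValueError):
            ceac(s, [10.0, 5.0])

    def test_default_grid_spans_three_gdp(self):
        grid = default_lambda_grid(18_254.0)
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(3 * 18_254.0)
        assert len(grid) == 100


class TestPsa:
    def test_degenerate_distributions_reproduce_base_case(self, table, ctx):
        fixed = table.as_fixed()
        cea, _, _ = run_base_case(table, ctx)
        psa = run_psa(fixed, ctx, n_draws=2, seed=5)
        assert psa.delta_cost[0] == cea.delta_cost
        assert psa.delta_qalys[0] == cea.delta_qalys
        assert np.all(psa.delta_cost == psa.delta_cost[0])

    def test_seeded_psa_is_bit_reproducible(self, table, ctx):
        a = run_psa(table, ctx, n_draws=40, seed=9)
        b = run_psa(table, ctx, n_draws=40, seed=9)
        assert a.cost_eip.tobytes() == b.cost_eip.tobytes()
        assert a.qalys_caps.tobytes() == b.qalys_caps.tobytes()
        pd.testing.assert_frame_equal(a.parameters, b.parameters)

    def test_fixture_psa_concentrates_in_positive_qaly_half(self, table, ctx):
        psa = run_psa(table, ctx, n_draws=300, seed=2)
        q = quadrant_fractions(psa)
        assert q["NE"] + q["SE"] >= 0.99
        assert sum(q.values()) == 1.0

    def test_rr_draws_are_resampled_from_posterior_pool(self, table, ctx):
        pool = {"rr_remission": np.array([1.5]), "rr_relapse": np.array([0.5])}
        psa = run_psa(table, ctx, n_draws=10, seed=3, rr_draws=pool)
        assert (psa.parameters.rr_remission == 1.5).all()
        assert (psa.parameters.rr_relapse == 0.5).all()


class TestScenariosAndCurrency:
    def test_unknown_scenario_lists_valid_names(self, table, ctx):
        with pytest.raises(ValueError, match="base"):
            run_scenarios(table, ctx, names=["no_such_scenario"])

    def test_mortality_scenario_off_equals_base(self, table, ctx):
        rows = run_scenarios(table, ctx, names=["base", "mortality_effect"],
                             mortality_rr=1.0)
        assert rows.iloc[0].icer == rows.iloc[1].icer

    def test_longer_horizon_lowers_fixture_icer(self, table, ctx):
        rows = run_scenarios(table, ctx, names=["base", "lifetime_75"]).set_index("scenario")
        assert rows.loc["lifetime_75"].icer < rows.loc["base"].icer

    def test_currency_conversion(self):
        assert convert_currency(0.0) == 0.0
        assert convert_currency(100.0, CurrencyConfig(ppp_factor=1.0)) == 100.0
        # the derived PPP factor maps 1 GDPpc (R$ 18,254) to ~USD 9,000
        assert convert_currency(18_254.0) == pytest.approx(9_000, rel=0.002)

    def test_icer_per_remission_direct_division(self, table, ctx):
        _, res_e, res_c = run_base_case(table, ctx)
        value, label = icer_per_remission(res_e, res_c, ctx.discount_rate)
        d_rem = res_e.trace.occupancy[1, 1] - res_c.trace.occupancy[1, 1]
        d_cost = (res_e.cycle_costs[1] - res_c.cycle_costs[1]) / 1.03
        assert label == ""
        assert value == pytest.approx(d_cost / d_rem)

    def test_icer_per_remission_undefined_for_identical_strategies(self, table, ctx):
        _, _, res_c = run_base_case(table, ctx)
        value, label = icer_per_remission(res_c, res_c)
        assert label == "undefined" and np.isnan(value)

    def test_hand_computed_toy_ratio(self):
        from eipcea.markov import CohortResult, CohortTrace

        def toy(cost1, rem1):
            occ = np.zeros((2, 6))
            occ[0, 0] = 1.0
            occ[1, 0], occ[1, 1] = 1.0 - rem1, rem1
            return CohortResult(
                trace=CohortTrace(occupancy=occ, start_age=26),
                discounted_cost=cost1, discounted_qalys=0.0,
                cycle_costs=np.array([0.0, cost1]), cycle_qalys=np.zeros(2),
            )

        value, label = icer_per_remission(toy(150.0, 0.10), toy(50.0, 0.05),
                                          discount_rate=0.0)
        assert label == ""
        assert value == pytest.approx((150.0 - 50.0) / 0.05)  # 2,000 R$
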