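import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coloncea.economics import (
    EXTENDEDLY_DOMINATED,
    ON_FRONTIER,
    STRONGLY_DOMINATED,
    accrue_costs,
    compute_dalys,
    dalys_averted,
    discount_factor,
    evaluate_strategies,
    frontier_and_icers,
    intl_to_zar,
    nmb,
    select_optimal,
    zar_to_intl,
)
from coloncea.engine import CohortTrace, run_cohort
from coloncea.states import Stratum, build_state_space

from conftest import make_toy_params


class TestDiscounting:
    @pytest.mark.parametrize(
        "month,expected",
        [(0, 1.0), (12, 1 / 1.05), (24, 1 / 1.05**2)],
    )
    def test_closed_form(self, month, expected):
        assert discount_factor(month, 0.05) == pytest.approx(expected, abs=1e-9)

    def test_printed_values(self):
        assert discount_factor(12) == pytest.approx(0.952381, abs=1e-6)
        assert discount_factor(24) == pytest.approx(0.907029, abs=1e-6)

    def test_negative_month_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1)

    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=50))
    def test_discounted_never_exceeds_undiscounted(self, stream):
        months = np.arange(len(stream))
        stream = np.asarray(stream)
        assert (stream * discount_factor(months, 0.05)).sum() <= stream.sum() + 1e-9
        np.testing.assert_allclose(
            (stream * discount_factor(months, 0.0)).sum(), stream.sum()
        )


class TestCurrency:
    def test_ppp_unit(self):
        assert zar_to_intl(6.86) == pytest.approx(1.0)
        assert zar_to_intl(0.0) == 0.0
        assert zar_to_intl(686.0) == pytest.approx(100.0)

    def test_round_trip(self):
        x = 1234.5678
        assert intl_to_zar(zar_to_intl(x)) == pytest.approx(x, rel=1e-15)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            zar_to_intl(-1.0)
        with pytest.raises(ValueError):
            intl_to_zar(-1.0)


class TestCostAccrual:
    def test_all_zero_costs_give_zero(self):
        params = make_toy_params(p_rec=0.01, q_annual=0.02, d_crc=0.04)
        for name in ("NO_CHEMO", "CAPOX_3MO"):
            spec = params.strategies[name]
            trace = run_cohort(spec, params)
            assert accrue_costs(trace, spec, params) == 0.0

    def test_single_visit_indirect_cost_for_patient_and_caregiver(self):
        # one treatment visit, transport 6.03 + 8h x 2.52 wages, two persons
        params = make_toy_params(zero_indirect=False)
        spec = params.strategies["CAPOX_3MO"]
        spec.n_treatment_visits = 1
        trace = run_cohort(spec, params)
        cost = accrue_costs(trace, spec, params)
        assert params.indirect.per_visit() == pytest.approx(52.38)
        assert cost == pytest.approx((6.03 + 8 * 2.52) * 2, abs=1e-9)

    def test_flat_cost_times_trapezoidal_person_months(self):
        c = 17.5
        params = make_toy_params(q_annual=1 - 0.99**12)
        params.surveillance_monthly_cost = c
        spec = params.strategies["NO_CHEMO"]
        trace = run_cohort(spec, params)
        df = trace.disease_free_occupancy()
        expected = c * (0.5 * (df[:-1] + df[1:])).sum()
        assert accrue_costs(trace, spec, params) == pytest.approx(expected, rel=1e-12)

    def test_hepatectomy_one_time_cost_on_recurrence_entries(self):
        params = make_toy_params(p_rec=0.02, cure_month=300)
        params.hepatectomy_cost = 9000.0
        spec = params.strategies["CAPOX_3MO"]
        trace = run_cohort(spec, params)
        space = trace.space
        rec0 = [space.recurrence(s, 0) for s in Stratum]
        entries = trace.entry_flux[:, rec0].sum()
        expected = entries * 9000.0 / 9.0  # 1/3 liver-only x 1/3 resected
        assert accrue_costs(trace, spec, params) == pytest.approx(expected, rel=1e-12)


class TestDALYs:
    def test_zero_weights_and_no_crc_deaths_give_zero(self):
        params = make_toy_params(p_rec=0.01, q_annual=0.05)
        spec = params.strategies["NO_CHEMO"]
        trace = run_cohort(spec, params)
        assert compute_dalys(trace, spec, params).total == 0.0

    def _manual_trace(self, params, state_code, rows):
        space = build_state_space(params.tunnel_depth, params.horizon_months)
        occ = np.zeros((params.horizon_months + 1, space.n_states))
        occ[rows, state_code] = 1.0
        return CohortTrace(space, "toy", occ, np.zeros_like(occ))

    def test_twelve_undiscounted_months_in_crc_death_is_one_daly(self):
        params = make_toy_params()
        space = build_state_space(params.tunnel_depth, params.horizon_months)
        trace = self._manual_trace(params, space.death_crc, slice(100, 112))
        d = compute_dalys(trace, params.strategies["NO_CHEMO"], params)
        assert d.total == pytest.approx(1.0, abs=1e-12)
        assert d.yll == pytest.approx(1.0, abs=1e-12)
        assert d.yld == 0.0

    def test_recurrence_person_months_times_weight(self):
        params = make_toy_params(dw_recurrence=0.2)
        space = build_state_space(params.tunnel_depth, params.horizon_months)
        # tunnel month 20: past both metastatic lines, so no adverse-event
        # disability is added on top of the recurrence weight
        code = space.recurrence(Stratum.LATE, 20)
        trace = self._manual_trace(params, code, slice(50, 74))
        d = compute_dalys(trace, params.strategies["NO_CHEMO"], params)
        assert d.yld == pytest.approx(24 * 0.2 / 12.0, abs=1e-12)
        assert d.yll == 0.0

    def test_daly_bounds(self, default_params):
        spec = default_params.strategies["NO_CHEMO"]
        trace = run_cohort(spec, default_params)
        d = compute_dalys(trace, spec, default_params)
        horizon_years = (
            discount_factor(np.arange(300), 0.05).sum() / 12.0
        )
        assert 0.0 <= d.total <= horizon_years

    def test_dalys_averted_subtraction_and_invariance(self):
        assert dalys_averted(10.0, 10.0) == 0.0
        assert dalys_averted(4.0, 9.74) == pytest.approx(5.74)
        assert dalys_averted(4.0 + 3.3, 9.74 + 3.3) == pytest.approx(5.74)


def _frontier_oracle(costs, effects):
    """Greedy lowest-ICER hull construction, independent of the
    dominance-removal implementation."""
    n = len(costs)
    cur = min(range(n), key=lambda i: (costs[i], -effects[i]))
    frontier = [cur]
    while True:
        cands = [i for i in range(n) if effects[i] > effects[cur]]
        if not cands:
            break
        cur = min(cands, key=lambda i: (costs[i] - costs[cur]) / (effects[i] - effects[cur]))
        frontier.append(cur)
    return set(frontier)


class TestFrontier:
    def test_two_points(self):
        out = frontier_and_icers(
            [{"strategy": "A", "cost": 0.0, "effect": 0.0},
             {"strategy": "B", "cost": 10.0, "effect": 1.0}]
        )
        assert set(out["dominance"]) == {ON_FRONTIER}
        assert out.set_index("strategy").loc["B", "icer"] == pytest.approx(10.0)

    def test_published_base_case_structure(self):
        out = frontier_and_icers(
            [
                {"strategy": "NO_CHEMO", "cost": 9959.24, "effect": 0.0},
                {"strategy": "CAPOX_3MO", "cost": 5381.17, "effect": 5.74},
                {"strategy": "FOLFOX_6MO", "cost": 22747.82, "effect": 5.91},
            ]
        ).set_index("strategy")
        assert out.loc["NO_CHEMO", "dominance"] == STRONGLY_DOMINATED
        assert out.loc["CAPOX_3MO", "dominance"] == ON_FRONTIER
        assert out.loc["FOLFOX_6MO", "dominance"] == ON_FRONTIER
        assert out.loc["FOLFOX_6MO", "icer"] > 13006.56

    def test_extended_dominance_detected(self):
        out = frontier_and_icers(
            [
                {"strategy": "A", "cost": 0.0, "effect": 0.0},
                {"strategy": "B", "cost": 9.0, "effect": 1.0},   # ICER 9
                {"strategy": "C", "cost": 10.0, "effect": 2.0},  # ICER 5 overall
            ]
        ).set_index("strategy")
        assert out.loc["B", "dominance"] == EXTENDEDLY_DOMINATED
        assert out.loc["C", "icer"] == pytest.approx(5.0)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            frontier_and_icers(
                [{"strategy": "A", "cost": 0, "effect": 0},
                 {"strategy": "A", "cost": 1, "effect": 1}]
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        costs = rng.uniform(0, 100, n)
        effects = rng.uniform(0, 10, n)
        df = frontier_and_icers(
            [{"strategy": f"s{i}", "cost": costs[i], "effect": effects[i]}
             for i in range(n)]
        )
        got = {int(s[1:]) for s in df.loc[df["dominance"] == ON_FRONTIER, "strategy"]}
        assert got == _frontier_oracle(costs, effects)

    def test_frontier_icers_strictly_increase(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 10))
            df = frontier_and_icers(
                [{"strategy": f"s{i}", "cost": rng.uniform(0, 100),
                  "effect": rng.uniform(0, 10)} for i in range(n)]
            )
            icers = (
                df[df["dominance"] == ON_FRONTIER]
                .sort_values("effect")["icer"]
                .dropna()
                .to_numpy()
            )
            assert np.all(np.diff(icers) > 0)


class TestNMBAndSelection:
    def test_formula(self):
        assert nmb(13006.56, 0.0, 0.0) == 0.0
        assert nmb(10.0, 2.0, 5.0) == pytest.approx(15.0)

    @given(st.tuples(st.floats(0, 1e5), st.floats(-10, 10), st.floats(0, 1e5)))
    def test_formula_identity(self, triple):
        w, e, c = triple
        assert nmb(w, e, c) == w * e - c

    def test_single_strategy(self):
        t = pd.DataFrame([{"strategy": "A", "cost": 5.0, "effect": 1.0}])
        assert select_optimal(t, 100.0) == "A"

    def test_icer_above_wtp_prefers_cheaper(self):
        t = pd.DataFrame(
            [{"strategy": "A", "cost": 0.0, "effect": 0.0},
             {"strategy": "B", "cost": 100.0, "effect": 1.0}]
        )
        assert select_optimal(t, 50.0) == "A"
        assert select_optimal(t, 200.0) == "B"

    @pytest.mark.parametrize("seed", range(10))
    def test_nmb_argmax_equals_frontier_icer_rule(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 8))
        t = pd.DataFrame(
            [{"strategy": f"s{i}", "cost": rng.uniform(0, 100),
              "effect": rng.uniform(0, 10)} for i in range(n)]
        )
        wtp = rng.uniform(1, 50)
        annotated = frontier_and_icers(t).sort_values("effect")
        front = annotated[annotated["dominance"] == ON_FRONTIER]
        affordable = front[front["icer"].fillna(-np.inf) <= wtp]
        rule = affordable.iloc[-1]["strategy"]
        assert select_optimal(t, wtp) == rule


def test_evaluate_strategies_requires_comparator(default_params):
    with pytest.raises(Exception, match="NO_CHEMO"):
        evaluate_strategies(default_params, ["CAPOX_3MO", "FOLFOX_6MO"])


def test_comparator_has_zero_dalys_averted(base_results):
    t = base_results.table.set_index("strategy")
    assert t.loc["NO_CHEMO", "dalys_averted"] == 0.0
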