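import math

import numpy as np
import pytest

from coloncea.engine import (
    CohortTrace,
    build_transition_tensors,
    half_cycle_weights,
    overall_survival_years,
    run_cohort,
    transition_row,
)
from coloncea.states import STRATA, Stratum, build_state_space

from conftest import make_toy_params


def _space(params):
    return build_state_space(params.tunnel_depth, params.horizon_months)


class TestTransitionRow:
    def test_absorbing_states_are_identity(self):
        params = make_toy_params(p_rec=0.02, q_annual=0.1, d_crc=0.05)
        space = _space(params)
        spec = params.strategies["CAPOX_3MO"]
        for code in space.absorbing:
            row = transition_row(code, 10, params, spec, space)
            assert row[code] == 1.0 and row.sum() == 1.0

    def test_no_recurrence_beyond_cure_month(self):
        params = make_toy_params(p_rec=0.02, q_annual=0.1, cure_month=96)
        space = _space(params)
        spec = params.strategies["CAPOX_3MO"]
        row = transition_row(space.disease_free, 100, params, spec, space)
        rec_codes = [c for c in range(space.n_states) if space.is_recurrence(c)]
        assert row[rec_codes].sum() == 0.0
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_competing_risk_rate_combination_hand_arithmetic(self):
        # monthly recurrence 0.02 and background 0.01, combined on the rate
        # scale and apportioned by rate share
        q_annual = 1.0 - 0.99**12  # gives monthly background exactly 0.01
        params = make_toy_params(p_rec=0.02, q_annual=q_annual)
        space = _space(params)
        spec = params.strategies["CAPOX_3MO"]
        row = transition_row(space.disease_free, 5, params, spec, space)
        r1, r2 = -math.log(0.98), -math.log(0.99)
        stay = math.exp(-(r1 + r2))
        p_exit = 1.0 - stay
        assert row[space.disease_free] == pytest.approx(stay, abs=1e-12)
        assert row[space.recurrence(Stratum.EARLY, 0)] == pytest.approx(
            p_exit * r1 / (r1 + r2), abs=1e-12
        )
        assert row[space.death_other] == pytest.approx(
            p_exit * r2 / (r1 + r2), abs=1e-12
        )
        assert row[space.disease_free] == pytest.approx(0.9702, abs=5e-5)

    def test_stratum_entry_follows_model_month(self):
        params = make_toy_params(p_rec=0.02)
        space = _space(params)
        spec = params.strategies["CAPOX_3MO"]
        for month, stratum in ((10, Stratum.EARLY), (30, Stratum.MID), (50, Stratum.LATE)):
            row = transition_row(space.disease_free, month, params, spec, space)
            assert row[space.recurrence(stratum, 0)] > 0

    def test_tensors_match_scalar_reference(self):
        from coloncea.synthetic import random_parameter_set

        params = random_parameter_set(11)
        space = _space(params)
        spec = params.strategies["FOLFOX_6MO"]
        tens = build_transition_tensors(spec, params, space)
        rng = np.random.default_rng(0)
        states = [space.disease_free, space.death_crc, space.death_other] + [
            space.recurrence(s, int(k))
            for s in STRATA
            for k in rng.integers(0, space.tunnel_depth, 3)
        ]
        for m in (0, 24, 25, 36, 37, 95, 96, 150, 299):
            for st in states:
                row = transition_row(st, m, params, spec, space)
                vec = np.zeros(space.n_states)
                vec[tens.t_stay[st]] += tens.p_stay[m, st]
                vec[tens.t_event[m, st]] += tens.p_event[m, st]
                vec[space.death_other] += tens.p_other[m, st]
                np.testing.assert_allclose(vec, row, atol=1e-13)


class TestRunCohort:
    def test_nothing_happens_until_terminal_forcing(self):
        params = make_toy_params()
        trace = run_cohort(params.strategies["NO_CHEMO"], params)
        df = trace.disease_free_occupancy()
        assert np.all(df[:-1] == 1.0)
        assert df[-1] == 0.0  # everyone dead at age 85
        assert trace.occupancy[-1, trace.space.death_other] == 1.0

    def test_constant_recurrence_geometric_decay(self):
        p = 0.013
        params = make_toy_params(p_rec=p, cure_month=300)
        trace = run_cohort(params.strategies["CAPOX_3MO"], params)
        t = np.arange(300)
        np.testing.assert_allclose(
            trace.disease_free_occupancy()[:-1], (1 - p) ** t, rtol=1e-12
        )

    def test_row_sums_and_monotonicity(self):
        from coloncea.synthetic import random_parameter_set

        params = random_parameter_set(5)
        trace = run_cohort(params.strategies["CAPOX_6MO"], params)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, list(trace.space.absorbing)].sum(axis=1)
        assert np.all(np.diff(dead) >= -1e-15)
        assert np.all(np.diff(trace.disease_free_occupancy()) <= 1e-15)
        assert np.all(trace.occupancy >= 0)

    def test_terminal_alive_mass_zero(self):
        from coloncea.synthetic import random_parameter_set

        params = random_parameter_set(7)
        trace = run_cohort(params.strategies["NO_CHEMO"], params)
        assert trace.alive_occupancy()[-1] == 0.0

    def test_cure_stops_recurrence_incidence(self):
        from coloncea.synthetic import random_parameter_set

        params = random_parameter_set(9)
        trace = run_cohort(params.strategies["FULV_6MO"], params)
        space = trace.space
        rec0 = [space.recurrence(s, 0) for s in STRATA]
        inc = trace.entry_flux[:, rec0].sum(axis=1)
        assert np.all(inc[params.cure_month + 1:] == 0.0)
        assert inc.sum() == pytest.approx(inc[: params.cure_month + 1].sum())

    def test_entry_flux_matches_df_outflow(self):
        p = 0.02
        params = make_toy_params(p_rec=p, cure_month=300)
        trace = run_cohort(params.strategies["CAPOX_3MO"], params)
        space = trace.space
        rec0 = [space.recurrence(s, 0) for s in STRATA]
        df = trace.disease_free_occupancy()
        # new recurrence entries at boundary t+1 = DF(t) * p (no competing risk)
        inc = trace.entry_flux[1:-1, rec0].sum(axis=1)
        np.testing.assert_allclose(inc, df[:-2] * p, rtol=1e-12)


class TestHalfCycleAndSurvival:
    def _trace_with_df(self, occ_df):
        space = build_state_space(1, len(occ_df) - 1)
        occ = np.zeros((len(occ_df), space.n_states))
        occ[:, space.disease_free] = occ_df
        occ[:, space.death_other] = 1.0 - occ_df
        return CohortTrace(space, "toy", occ, np.zeros_like(occ))

    def test_constant_occupancy_gives_constant_weights(self):
        trace = self._trace_with_df(np.full(11, 0.37))
        w = half_cycle_weights(trace)
        np.testing.assert_allclose(w[:, trace.space.disease_free], 0.37)

    def test_step_drop_accrues_half(self):
        occ_df = np.array([1.0, 0.0, 0.0])
        trace = self._trace_with_df(occ_df)
        w = half_cycle_weights(trace)
        assert w[0, trace.space.disease_free] == 0.5
        assert w[1, trace.space.disease_free] == 0.0

    def test_exponential_decay_matches_analytic_integral(self):
        lam = 0.05
        t = np.arange(301)
        trace = self._trace_with_df(np.exp(-lam * t))
        w = half_cycle_weights(trace)
        accrued = w[:, trace.space.disease_free].sum()
        exact = (1 - math.exp(-lam * 300)) / lam
        assert abs(accrued - exact) / exact < 1e-3

    def test_everyone_dies_first_cycle_gives_half_month(self):
        params = make_toy_params(q_annual=1.0)
        trace = run_cohort(params.strategies["NO_CHEMO"], params)
        assert overall_survival_years(trace) == pytest.approx(0.5 / 12.0, abs=1e-12)

    def test_no_deaths_before_terminal_forcing_gives_about_25_years(self):
        params = make_toy_params()
        trace = run_cohort(params.strategies["NO_CHEMO"], params)
        os_y = overall_survival_years(trace)
        assert os_y == pytest.approx(299.5 / 12.0, abs=1e-9)
        assert os_y == pytest.approx(25.0, abs=0.05)

    def test_constant_mortality_matches_geometric_trapezoid_sum(self):
        q_annual = 1.0 - 0.99**12  # monthly all-cause death exactly 0.01
        params = make_toy_params(q_annual=q_annual)
        trace = run_cohort(params.strategies["NO_CHEMO"], params)
        surv = 0.99 ** np.arange(301)
        surv[300] = 0.0  # terminal forcing
        expected = (0.5 * (surv[:-1] + surv[1:])).sum() / 12.0
        assert overall_survival_years(trace) == pytest.approx(expected, rel=1e-12)
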