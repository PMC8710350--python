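import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coloncea.parameters import (
    COMPARATOR,
    IndirectCosts,
    MetastaticCare,
    ParameterSet,
    StrategyCosts,
    StrategySpec,
    TraeEvent,
)
from coloncea.states import STRATA

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_toy_params(
    p_rec: float = 0.0,
    q_annual: float = 0.0,
    d_crc: float = 0.0,
    cure_month: int = 300,
    discount: float = 0.0,
    dw_recurrence: float = 0.0,
    tunnel_depth: int = 60,
    treated: str = "CAPOX_3MO",
    zero_indirect: bool = True,
) -> ParameterSet:
    """Minimal valid two-arm ParameterSet with every cost zeroed, for
    closed-form checks; individual pieces are switched on per test."""
    params = ParameterSet(
        cure_month=cure_month,
        discount_rate_annual=discount,
        tunnel_depth=tunnel_depth,
        surveillance_monthly_cost=0.0,
        surveillance_visits_per_month=0.0,
        hepatectomy_cost=0.0,
        hepatectomy_disability_weight=0.0,
    )
    params.background_mortality = {a: q_annual for a in range(60, 85)}
    params.background_mortality[85] = 1.0
    rec = np.zeros(params.horizon_months)
    rec[:cure_month] = p_rec
    zero_traes = [TraeEvent(f"ev{i}", 0.0, 0.0, 0.0, 1.0) for i in range(6)]
    for name, dur, visits in ((COMPARATOR, 0, 0), (treated, 3, 4)):
        params.strategies[name] = StrategySpec(name, dur, visits)
        params.recurrence_prob[name] = rec.copy()
        params.recurrence_multiplier[name] = 1.0
        params.costs[name] = StrategyCosts()
        params.trae_adjuvant[name] = [
            TraeEvent(e.name, e.probability, e.cost, e.disability_weight, e.duration_months)
            for e in zero_traes
        ]
    for s in STRATA:
        params.crc_death_prob[s.value] = np.full(tunnel_depth, d_crc)
    params.metastatic = MetastaticCare(
        line1_monthly_cost=0.0, line2_monthly_cost=0.0, bsc_monthly_cost=0.0,
        visits_per_month_on_treatment=0.0, visits_per_month_bsc=0.0,
    )
    if zero_indirect:
        params.indirect = IndirectCosts(
            transport_round_trip=0.0, hourly_wage=0.0, hours_per_visit=0.0, persons=2
        )
    params.disability_weights["recurrence"] = dw_recurrence
    params.validate()
    return params


@pytest.fixture(scope="session")
def default_params():
    from coloncea.synthetic import generate_parameter_set

    return generate_parameter_set()


@pytest.fixture(scope="session")
def base_results(default_params):
    from coloncea.model import MarkovCEA

    return MarkovCEA(default_params).fit()
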