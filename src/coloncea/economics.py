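"""Cost and DALY accrual, discounting, and comparative cost-effectiveness.

Costs are societal (2020 international dollars, I$): direct medical
costs of adjuvant treatment, surveillance, metastatic chemotherapy,
adverse events and hepatectomy, plus indirect costs (transport and a
day of lost wages per clinic visit for the patient and one caregiver).

Health outcomes are disability-adjusted life-years without
age-weighting: years lived with disability use state disability weights
on a 0 (no disability) to 1 (death from colon cancer) scale, and years
of life lost accrue at weight one while the cohort sits in the
colon-cancer-death state, up to the model horizon (age 85).  Costs and
DALYs are discounted at 5%/year; overall survival is not.

Comparative outputs follow standard decision-analytic practice:
strategies are placed on the cost-effect plane, strongly and extendedly
dominated options are removed, pairwise ICERs are computed along the
efficiency frontier, and net monetary benefit ranks strategies at a
willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CohortTrace, half_cycle_weights
from .parameters import (
    COMPARATOR,
    ZAR_PER_INTL,
    ParameterError,
    ParameterSet,
    StrategySpec,
)
from .states import STRATA, StateSpace

ON_FRONTIER = "on_frontier"
STRONGLY_DOMINATED = "strongly_dominated"
EXTENDEDLY_DOMINATED = "extendedly_dominated"


def discount_factor(month, annual_rate: float = 0.05):
    """Discount factor ``(1 + r)^(-month/12)``, applied identically to
    costs and health outcomes."""
    month = np.asarray(month, dtype=float)
    if np.any(month < 0):
        raise ValueError("month must be >= 0")
    out = (1.0 + annual_rate) ** (-month / 12.0)
    return float(out) if out.ndim == 0 else out


def zar_to_intl(amount_zar):
    """2020 South African rand to international dollars (ZAR 6.86 = I$1)."""
    if np.any(np.asarray(amount_zar) < 0):
        raise ValueError("amount must be >= 0")
    return amount_zar / ZAR_PER_INTL


def intl_to_zar(amount_intl):
    if np.any(np.asarray(amount_intl) < 0):
        raise ValueError("amount must be >= 0")
    return amount_intl * ZAR_PER_INTL


def nmb(wtp: float, effect: float, cost: float) -> float:
    """Net monetary benefit: WTP x effectiveness - cost."""
    return wtp * effect - cost


# ------------------------------------------------------------------ accrual rates


def _require(params: ParameterSet, strategy: str, attr: str, container: dict):
    if strategy not in container:
        raise ParameterError(f"cost schedule missing component {attr}.{strategy}")
    return container[strategy]


def _metastatic_phase_vectors(params: ParameterSet, space: StateSpace):
    """Per-tunnel-month metastatic cost and disability rates (same for
    every stratum): first line, second line, then best supportive care."""
    met = params.metastatic
    D = space.tunnel_depth
    ipv = params.indirect.per_visit()
    cost_k = np.empty(D)
    dw_k = np.empty(D)
    trae1_c = sum(ev.expected_cost() for ev in met.trae_line1)
    trae2_c = sum(ev.expected_cost() for ev in met.trae_line2)
    trae1_d = sum(ev.expected_disability_months() for ev in met.trae_line1)
    trae2_d = sum(ev.expected_disability_months() for ev in met.trae_line2)
    base_dw = params.disability_weights["recurrence"]
    for k in range(D):
        if k < met.line1_months:
            cost_k[k] = (
                met.line1_monthly_cost
                + trae1_c / max(met.line1_months, 1)
                + met.visits_per_month_on_treatment * ipv
            )
            dw_k[k] = base_dw + trae1_d / max(met.line1_months, 1)
        elif k < met.line1_months + met.line2_months:
            cost_k[k] = (
                met.line2_monthly_cost
                + trae2_c / max(met.line2_months, 1)
                + met.visits_per_month_on_treatment * ipv
            )
            dw_k[k] = base_dw + trae2_d / max(met.line2_months, 1)
        else:
            cost_k[k] = met.bsc_monthly_cost + met.visits_per_month_bsc * ipv
            dw_k[k] = base_dw
    return cost_k, np.clip(dw_k, 0.0, 1.0)


def cost_rate_matrix(
    strategy: StrategySpec, params: ParameterSet, space: StateSpace
) -> np.ndarray:
    """Monthly cost accrual rate per state and cycle, shape (n_states, horizon)."""
    H = params.horizon_months
    rate = np.zeros((space.n_states, H))
    ipv = params.indirect.per_visit()

    # disease-free: surveillance always; adjuvant bundle during treatment
    df_rate = np.full(
        H,
        params.surveillance_monthly_cost
        + params.surveillance_visits_per_month * ipv,
    )
    dur = strategy.adjuvant_duration_months
    if dur > 0:
        sched = _require(params, strategy.name, "costs", params.costs)
        trae = _require(params, strategy.name, "trae_adjuvant", params.trae_adjuvant)
        trae_monthly = sum(ev.expected_cost() for ev in trae) / dur
        visits_monthly = strategy.n_treatment_visits / dur
        df_rate[:dur] += (
            sched.monthly_total(dur) + trae_monthly + visits_monthly * ipv
        )
    rate[space.disease_free] = df_rate

    cost_k, _ = _metastatic_phase_vectors(params, space)
    for s in STRATA:
        for k in range(space.tunnel_depth):
            rate[space.recurrence(s, k), :] = cost_k[k]
    return rate


def entry_cost_vector(params: ParameterSet, space: StateSpace) -> np.ndarray:
    """One-time cost per unit of entry flux into each state: hepatectomy
    for the liver-only fraction proceeding to curative-intent resection."""
    vec = np.zeros(space.n_states)
    frac = params.liver_only_fraction * params.hepatectomy_fraction_of_liver_only
    for s in STRATA:
        vec[space.recurrence(s, 0)] = frac * params.hepatectomy_cost
    return vec


def disability_matrix(
    strategy: StrategySpec, params: ParameterSet, space: StateSpace
) -> np.ndarray:
    """Disability weight per state and cycle (includes weight-1 accrual in
    the colon-cancer-death state, i.e. years of life lost)."""
    H = params.horizon_months
    w = np.zeros((space.n_states, H))
    dws = params.disability_weights
    df_w = np.full(H, dws["disease_free"])
    dur = strategy.adjuvant_duration_months
    if dur > 0:
        trae = _require(params, strategy.name, "trae_adjuvant", params.trae_adjuvant)
        df_w[:dur] += sum(ev.expected_disability_months() for ev in trae) / dur
    w[space.disease_free] = np.clip(df_w, 0.0, 1.0)

    _, dw_k = _metastatic_phase_vectors(params, space)
    for s in STRATA:
        for k in range(space.tunnel_depth):
            w[space.recurrence(s, k), :] = dw_k[k]
    w[space.death_crc, :] = dws["death_crc"]
    w[space.death_other, :] = dws["death_other"]
    return w


def entry_disability_vector(params: ParameterSet, space: StateSpace) -> np.ndarray:
    """One-time DALY increment (years) per unit entry flux: transient
    post-hepatectomy disability for the resected fraction."""
    vec = np.zeros(space.n_states)
    frac = params.liver_only_fraction * params.hepatectomy_fraction_of_liver_only
    dw_years = (
        params.hepatectomy_disability_weight
        * params.hepatectomy_disability_months
        / 12.0
    )
    for s in STRATA:
        vec[space.recurrence(s, 0)] = frac * dw_years
    return vec


# ------------------------------------------------------------------ accrual


def _discount_vectors(params: ParameterSet, H: int):
    cyc = discount_factor(np.arange(H), params.discount_rate_annual)
    bnd = discount_factor(np.arange(H + 1), params.discount_rate_annual)
    return np.atleast_1d(cyc), np.atleast_1d(bnd)


def accrue_costs(
    trace: CohortTrace, strategy: StrategySpec, params: ParameterSet
) -> float:
    """Discounted lifetime societal cost per patient, I$."""
    space = trace.space
    w = half_cycle_weights(trace)  # (H, S)
    rate = cost_rate_matrix(strategy, params, space)  # (S, H)
    disc, disc_b = _discount_vectors(params, trace.horizon)
    recurring = float(np.einsum("ts,st,t->", w, rate, disc))
    onetime = float((trace.entry_flux @ entry_cost_vector(params, space)) @ disc_b)
    return recurring + onetime


@dataclass
class DALYBreakdown:
    total: float
    yll: float
    yld: float


def compute_dalys(
    trace: CohortTrace, strategy: StrategySpec, params: ParameterSet
) -> DALYBreakdown:
    """Discounted DALYs per patient: YLL (weight-1 years in the cancer-death
    state until the horizon) + YLD (weighted alive person-time, including
    transient adverse-event and post-hepatectomy disability)."""
    space = trace.space
    w = half_cycle_weights(trace)
    wmat = disability_matrix(strategy, params, space)
    disc, disc_b = _discount_vectors(params, trace.horizon)

    per_state = np.einsum("ts,st,t->s", w, wmat, disc) / 12.0
    yll = float(per_state[space.death_crc])
    yld = float(per_state.sum() - yll - per_state[space.death_other])
    yld += float(
        (trace.entry_flux * entry_disability_vector(params, space)).sum(axis=1) @ disc_b
    )
    return DALYBreakdown(total=yll + yld, yll=yll, yld=yld)


def dalys_averted(strategy_dalys: float, comparator_dalys: float) -> float:
    """Health gained vs the comparator (no adjuvant chemotherapy)."""
    return comparator_dalys - strategy_dalys


# ------------------------------------------------------------------ frontier


def frontier_and_icers(entries: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Dominance analysis on the cost-effect plane.

    ``entries`` needs columns/keys ``strategy``, ``cost``, ``effect``.
    Returns the same rows with ``dominance`` labels and pairwise ``icer``
    along the efficiency frontier (NaN for the cheapest frontier point).

    Strong dominance (costlier, no more effective) is removed first;
    extended dominance (an ICER above that of a more effective strategy)
    is removed iteratively.  On equal effect the cheaper strategy is
    kept; on identical (cost, effect) both stay and are flagged.
    """
    df = pd.DataFrame(entries).copy()
    if df["strategy"].duplicated().any():
        dup = df.loc[df["strategy"].duplicated(), "strategy"].iloc[0]
        raise ValueError(f"duplicate strategy name {dup!r}")
    if len(df) < 2:
        raise ValueError("frontier analysis needs at least two strategies")
    df["dominance"] = ON_FRONTIER
    df["icer"] = np.nan
    df["equivalent"] = False

    cost = df["cost"].to_numpy(float)
    eff = df["effect"].to_numpy(float)
    n = len(df)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if cost[j] == cost[i] and eff[j] == eff[i]:
                df.loc[df.index[i], "equivalent"] = True
                continue
            if cost[j] <= cost[i] and eff[j] >= eff[i]:
                df.loc[df.index[i], "dominance"] = STRONGLY_DOMINATED
                break

    def _frontier_order(sub: pd.DataFrame) -> pd.DataFrame:
        return sub.sort_values(["effect", "cost"], kind="mergesort")

    live = df[df["dominance"] == ON_FRONTIER]
    while True:
        live = _frontier_order(live)
        c = live["cost"].to_numpy(float)
        e = live["effect"].to_numpy(float)
        if len(live) < 3:
            break
        icers = (c[1:] - c[:-1]) / (e[1:] - e[:-1])
        bad = np.flatnonzero(icers[:-1] >= icers[1:])
        if bad.size == 0:
            break
        df.loc[live.index[bad[0] + 1], "dominance"] = EXTENDEDLY_DOMINATED
        live = df[df["dominance"] == ON_FRONTIER]

    live = _frontier_order(df[df["dominance"] == ON_FRONTIER])
    c = live["cost"].to_numpy(float)
    e = live["effect"].to_numpy(float)
    if len(live) > 1:
        df.loc[live.index[1:], "icer"] = (c[1:] - c[:-1]) / (e[1:] - e[:-1])
    return df


def select_optimal(table: pd.DataFrame, wtp: float) -> str:
    """Strategy with maximal net monetary benefit at the given WTP
    (ties go to the cheaper strategy)."""
    if len(table) == 0:
        raise ValueError("no strategies to select from")
    nmbs = wtp * table["effect"].to_numpy(float) - table["cost"].to_numpy(float)
    order = np.lexsort((table["cost"].to_numpy(float), -nmbs))
    return str(table["strategy"].iloc[order[0]])


# ------------------------------------------------------------------ evaluation


def evaluate_strategies(
    params: ParameterSet,
    strategies: list[str] | None = None,
    wtp: float | None = None,
    keep_traces: bool = False,
):
    """Run the cohort engine and economic accrual for every strategy and
    assemble the comparative table (cost, DALYs averted, OS, dominance,
    ICER, NMB), with the no-chemotherapy arm as comparator.
    """
    from .engine import overall_survival_years, run_cohort
    from .states import build_state_space

    if strategies is None:
        strategies = params.strategy_names()
    if COMPARATOR not in strategies:
        raise ParameterError(f"strategy list must include the comparator {COMPARATOR}")
    space = build_state_space(params.tunnel_depth, params.horizon_months)
    rows = []
    traces: dict[str, CohortTrace] = {}
    for name in strategies:
        spec = params.strategies[name]
        trace = run_cohort(spec, params, space)
        d = compute_dalys(trace, spec, params)
        rows.append(
            {
                "strategy": name,
                "cost": accrue_costs(trace, spec, params),
                "dalys": d.total,
                "yll": d.yll,
                "yld": d.yld,
                "os_years": overall_survival_years(trace),
            }
        )
        if keep_traces:
            traces[name] = trace
    table = pd.DataFrame(rows)
    comp_dalys = float(table.loc[table["strategy"] == COMPARATOR, "dalys"].iloc[0])
    table["effect"] = comp_dalys - table["dalys"]  # DALYs averted vs NO_CHEMO
    annotated = frontier_and_icers(table[["strategy", "cost", "effect"]])
    table = table.merge(
        annotated[["strategy", "dominance", "icer", "equivalent"]], on="strategy"
    )
    w = params.wtp if wtp is None else wtp
    table["nmb"] = w * table["effect"] - table["cost"]
    table = table.rename(columns={"effect": "dalys_averted"})
    if keep_traces:
        return table, traces
    return table
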