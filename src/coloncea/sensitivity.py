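"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the full comparative analysis with one parameter at
its low and high bound and reports the movement of the headline ICER
(the next frontier strategy versus the optimal one) in a tornado table.

The PSA redraws all parameters with attached distributions
simultaneously (beta for probabilities and disability weights, gamma
for costs, log-normal mean-one multipliers for recurrence hazards),
re-evaluates every strategy per iteration, and summarises the
probability that each strategy is optimal; the cost-effectiveness
acceptability curve re-scores the stored draws over a willingness-to-pay
grid without re-simulating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import ON_FRONTIER, evaluate_strategies, select_optimal
from .parameters import WTP_HIGH, WTP_LOW, ParameterError, ParameterSet


@dataclass
class DSARange:
    """One-way range for a dotted parameter path; ``low <= base <= high``."""

    path: str
    low: float
    high: float
    base: float | None = None

    def resolved_base(self, params: ParameterSet) -> float:
        b = self.base if self.base is not None else float(params.get_path(self.path))
        if not self.low <= b <= self.high:
            raise ParameterError(
                f"DSA range for {self.path}: low <= base <= high violated "
                f"({self.low}, {b}, {self.high})"
            )
        return b


def headline_icer(table: pd.DataFrame, wtp: float) -> tuple[float, str]:
    """The tornado's output statistic: the ICER of the frontier strategy
    just above the NMB-optimal one (or the optimal's own ICER when it is
    the most effective frontier point), plus the optimal strategy name."""
    table = table.rename(columns={"dalys_averted": "effect"}, errors="ignore")
    opt = select_optimal(table, wtp)
    frontier = table[table["dominance"] == ON_FRONTIER].sort_values("effect")
    opt_row = table[table["strategy"] == opt].iloc[0]
    above = frontier[frontier["effect"] > opt_row["effect"]]
    if len(above):
        return float(above.iloc[0]["icer"]), opt
    own = frontier[frontier["strategy"] == opt]
    if len(own):
        return float(own.iloc[0]["icer"]), opt
    return float("nan"), opt


def one_way_dsa(
    ranges: list[DSARange],
    params: ParameterSet,
    strategies: list[str] | None = None,
    wtp: float | None = None,
) -> pd.DataFrame:
    """Tornado table: one row per parameter, sorted by ICER swing."""
    wtp_val = params.wtp if wtp is None else wtp
    base_table = evaluate_strategies(params, strategies, wtp_val)
    base_icer, base_opt = headline_icer(base_table, wtp_val)
    rows = []
    for r in ranges:
        r.resolved_base(params)
        end = {}
        for label, value in (("low", r.low), ("high", r.high)):
            p = params.copy()
            p.set_path(r.path, value)
            p.validate()
            table = evaluate_strategies(p, strategies, wtp_val)
            end[label] = headline_icer(table, wtp_val)
        rows.append(
            {
                "parameter": r.path,
                "low": r.low,
                "high": r.high,
                "icer_low": end["low"][0],
                "icer_high": end["high"][0],
                "optimal_low": end["low"][1],
                "optimal_high": end["high"][1],
                "optimal_changed": end["low"][1] != base_opt
                or end["high"][1] != base_opt,
                "swing": abs(end["high"][0] - end["low"][0]),
            }
        )
    out = pd.DataFrame(rows).sort_values("swing", ascending=False, kind="mergesort")
    out.attrs["base_icer"] = base_icer
    out.attrs["base_optimal"] = base_opt
    return out.reset_index(drop=True)


def draw_parameter_set(base: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA draw: entries with attached distributions are resampled,
    everything else keeps its base value; the result is re-validated."""
    drawn = base.copy()
    for path, spec in base.psa_distributions.items():
        cur = float(base.get_path(path))
        drawn.set_path(path, spec.sample(rng, cur))
    drawn.validate()
    return drawn


@dataclass
class PSAResult:
    samples: pd.DataFrame  # iteration, strategy, cost, effect
    wtp: float
    seed: int
    n: int
    optimal: pd.Series = field(init=False)  # iteration -> strategy
    probability_optimal: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.optimal = _argmax_nmb(self.samples, self.wtp)
        counts = self.optimal.value_counts()
        strategies = self.samples["strategy"].unique()
        self.probability_optimal = (
            counts.reindex(strategies, fill_value=0) / self.n
        ).rename("probability_optimal")


def _argmax_nmb(samples: pd.DataFrame, wtp: float) -> pd.Series:
    s = samples.assign(nmb=wtp * samples["effect"] - samples["cost"])
    idx = s.groupby("iteration")["nmb"].idxmax()
    return pd.Series(
        s.loc[idx, "strategy"].to_numpy(), index=idx.index, name="optimal"
    )


#: parameter-path prefixes whose variation changes transition probabilities
#: (anything else only affects accrual, so cohort traces can be reused)
_TRANSITION_PREFIXES = (
    "recurrence_prob", "recurrence_multiplier", "crc_death_prob",
    "background_mortality", "cure_month", "tunnel_depth", "start_age",
    "horizon_months",
)


def run_psa(
    base: ParameterSet,
    n: int,
    seed: int,
    strategies: list[str] | None = None,
    wtp: float | None = None,
) -> PSAResult:
    """Monte Carlo PSA: ``n`` independent parameter draws, each fully
    re-evaluated; reproducible for a given seed.

    Cohort traces are re-simulated per draw only for strategies whose
    transition inputs carry a distribution; strategies whose drawn
    entries affect accrual alone reuse the base-case trace.
    """
    from .economics import COMPARATOR, accrue_costs, compute_dalys
    from .engine import run_cohort
    from .states import build_state_space

    if n < 1:
        raise ValueError("n must be >= 1")
    wtp_val = base.wtp if wtp is None else wtp
    if strategies is None:
        strategies = base.strategy_names()
    if COMPARATOR not in strategies:
        raise ParameterError(f"PSA strategy list must include {COMPARATOR}")
    rng = np.random.default_rng(seed)
    space = build_state_space(base.tunnel_depth, base.horizon_months)

    shared = ("crc_death_prob", "background_mortality", "cure_month",
              "tunnel_depth", "start_age", "horizon_months")
    shared_dynamic = any(
        p.split(".")[0] in shared for p in base.psa_distributions
    )
    cached = {}
    for name in strategies:
        per_strategy = any(
            p.startswith((f"recurrence_prob.{name}", f"recurrence_multiplier.{name}"))
            for p in base.psa_distributions
        )
        if not (per_strategy or shared_dynamic):
            cached[name] = run_cohort(base.strategies[name], base, space)

    k = len(strategies)
    costs = np.empty((n, k))
    dalys = np.empty((n, k))
    for it in range(n):
        drawn = draw_parameter_set(base, rng)
        for j, name in enumerate(strategies):
            spec = drawn.strategies[name]
            trace = cached.get(name)
            if trace is None:
                trace = run_cohort(spec, drawn, space)
            costs[it, j] = accrue_costs(trace, spec, drawn)
            dalys[it, j] = compute_dalys(trace, spec, drawn).total
    comp = strategies.index(COMPARATOR)
    effects = dalys[:, [comp]] - dalys
    samples = pd.DataFrame(
        {
            "iteration": np.repeat(np.arange(n), k),
            "strategy": np.tile(np.array(strategies, dtype=object), n),
            "cost": costs.ravel(),
            "effect": effects.ravel(),
        }
    )
    return PSAResult(samples=samples, wtp=wtp_val, seed=seed, n=n)


def ceac(
    psa: PSAResult | pd.DataFrame,
    wtp_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    Re-scores the stored (cost, effect) draws at each willingness-to-pay
    on the grid (default: 25 points from half to three times GDP per
    capita) and returns per-strategy probability-optimal columns indexed
    by WTP; rows sum to one.
    """
    samples = psa.samples if isinstance(psa, PSAResult) else psa
    if len(samples) == 0:
        raise ValueError("no PSA samples")
    if wtp_grid is None:
        wtp_grid = np.linspace(WTP_LOW, WTP_HIGH, 25)
    n_iter = samples["iteration"].nunique()
    strategies = list(samples["strategy"].unique())
    out = []
    for w in np.asarray(wtp_grid, dtype=float):
        winners = _argmax_nmb(samples, w)
        counts = winners.value_counts().reindex(strategies, fill_value=0)
        out.append(counts / n_iter)
    df = pd.DataFrame(out, index=pd.Index(np.asarray(wtp_grid, float), name="wtp"))
    return df
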