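"""Model/Results surface tying the pipeline together.

:class:`MarkovCEA` is constructed from a :class:`~coloncea.parameters.ParameterSet`
(directly, from a config file, or from the synthetic generator); ``fit()``
runs the cohort engine and economic accrual for every strategy and
returns a :class:`CEAResults` carrying the comparative table, traces,
and methods for sensitivity analysis and plotting.

    >>> from coloncea import MarkovCEA
    >>> res = MarkovCEA.from_synthetic(seed=0).fit()
    >>> print(res.summary())            # doctest: +SKIP
    >>> psa = res.run_psa(n=500, seed=1)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .economics import ON_FRONTIER, evaluate_strategies, select_optimal
from .parameters import COMPARATOR, ParameterSet
from .sensitivity import DSARange, PSAResult, ceac, one_way_dsa, run_psa

if TYPE_CHECKING:
    from .engine import CohortTrace


class MarkovCEA:
    """Decision-analytic Markov cohort cost-effectiveness model.

    Parameters
    ----------
    params : ParameterSet
        Complete, validated model inputs.
    strategies : list of str, optional
        Treatment arms to evaluate (default: all in ``params``); must
        include the no-chemotherapy comparator.
    wtp : float, optional
        Willingness-to-pay threshold, I$/DALY averted (default: the
        2020 ZA GDP per capita carried by ``params``).
    """

    def __init__(
        self,
        params: ParameterSet,
        strategies: list[str] | None = None,
        wtp: float | None = None,
    ) -> None:
        params.validate()
        self.params = params
        self.strategies = list(strategies) if strategies else params.strategy_names()
        if COMPARATOR not in self.strategies:
            raise ValueError(f"strategies must include {COMPARATOR}")
        self.wtp = params.wtp if wtp is None else float(wtp)

    @classmethod
    def from_synthetic(
        cls, seed: int = 0, risk: str = "base", scenario=None, **kwargs
    ) -> "MarkovCEA":
        from .synthetic import SyntheticScenario, generate_parameter_set

        scen = scenario if scenario is not None else SyntheticScenario(seed=seed)
        return cls(generate_parameter_set(scen, risk=risk), **kwargs)

    @classmethod
    def from_config(cls, path) -> "MarkovCEA":
        from .io import load_and_validate_config

        cfg, params = load_and_validate_config(path)
        return cls(params, strategies=cfg.strategies or None, wtp=cfg.wtp)

    def fit(self) -> "CEAResults":
        table, traces = evaluate_strategies(
            self.params, self.strategies, self.wtp, keep_traces=True
        )
        return CEAResults(model=self, table=table, traces=traces)


@dataclass
class CEAResults:
    """Fitted comparative results.

    ``table`` has one row per strategy: discounted lifetime cost (I$),
    DALYs and DALYs averted vs no chemotherapy, undiscounted OS years,
    dominance status, frontier ICER and net monetary benefit.
    """

    model: MarkovCEA
    table: pd.DataFrame
    traces: dict[str, "CohortTrace"] = field(default_factory=dict)

    @property
    def params(self) -> ParameterSet:
        return self.model.params

    @property
    def wtp(self) -> float:
        return self.model.wtp

    @property
    def frontier(self) -> pd.DataFrame:
        return (
            self.table[self.table["dominance"] == ON_FRONTIER]
            .sort_values("dalys_averted")
            .reset_index(drop=True)
        )

    @property
    def optimal_strategy(self) -> str:
        t = self.table.rename(columns={"dalys_averted": "effect"})
        return select_optimal(t, self.wtp)

    def summary(self) -> str:
        t = self.table.sort_values("dalys_averted")
        lines = [
            "Markov cohort cost-effectiveness results",
            "=" * 86,
            f"comparator: {COMPARATOR}    WTP: I${self.wtp:,.2f}/DALY averted    "
            f"discount: {self.params.discount_rate_annual:.0%}/yr",
            f"horizon: {self.params.horizon_months} months from age "
            f"{self.params.start_age}    parameters: {self.params.content_hash()}",
            "-" * 86,
            f"{'strategy':<18}{'cost I$':>12}{'DALYs averted':>15}"
            f"{'OS yrs':>9}{'ICER':>12}{'NMB I$':>12}  dominance",
            "-" * 86,
        ]
        for _, r in t.iterrows():
            icer = f"{r['icer']:,.0f}" if np.isfinite(r["icer"]) else "--"
            lines.append(
                f"{r['strategy']:<18}{r['cost']:>12,.2f}{r['dalys_averted']:>15.3f}"
                f"{r['os_years']:>9.2f}{icer:>12}{r['nmb']:>12,.0f}  {r['dominance']}"
            )
        lines.append("-" * 86)
        lines.append(f"optimal at WTP: {self.optimal_strategy}")
        return "\n".join(lines)

    # ------------------------------------------------------------- analyses

    def run_psa(self, n: int, seed: int, wtp: float | None = None) -> PSAResult:
        return run_psa(
            self.params, n=n, seed=seed, strategies=self.model.strategies,
            wtp=self.wtp if wtp is None else wtp,
        )

    def run_dsa(self, ranges: list[DSARange], wtp: float | None = None) -> pd.DataFrame:
        return one_way_dsa(
            ranges, self.params, strategies=self.model.strategies,
            wtp=self.wtp if wtp is None else wtp,
        )

    def ceac(self, psa: PSAResult, wtp_grid=None) -> pd.DataFrame:
        return ceac(psa, wtp_grid)

    # ------------------------------------------------------------- output

    def to_csv(self, path) -> None:
        cols = [
            "strategy", "cost", "dalys", "dalys_averted", "os_years",
            "dominance", "icer", "nmb",
        ]
        self.table[cols].to_csv(path, index=False)

    def plot_ce_plane(self, ax=None):
        from .plotting import plot_ce_plane

        return plot_ce_plane(self.table, wtp=self.wtp, ax=ax)
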