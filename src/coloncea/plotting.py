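"""Standard cost-effectiveness graphics (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .economics import ON_FRONTIER


def plot_ce_plane(table: pd.DataFrame, wtp: float | None = None, ax=None):
    """Cost-effectiveness plane: cost vs DALYs averted, frontier dashed."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    eff = table["dalys_averted"] if "dalys_averted" in table else table["effect"]
    ax.scatter(eff, table["cost"], color="tab:gray", zorder=3)
    for _, row in table.iterrows():
        e = row.get("dalys_averted", row.get("effect"))
        ax.annotate(row["strategy"], (e, row["cost"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    front = table[table["dominance"] == ON_FRONTIER].copy()
    front = front.sort_values("dalys_averted" if "dalys_averted" in front else "effect")
    fe = front["dalys_averted"] if "dalys_averted" in front else front["effect"]
    ax.plot(fe, front["cost"], "--", color="tab:blue", label="efficiency frontier")
    if wtp is not None:
        e = np.linspace(float(eff.min()), float(eff.max()), 10)
        base = float(front["cost"].iloc[0]) if len(front) else 0.0
        e0 = float(fe.iloc[0]) if len(front) else 0.0
        ax.plot(e, base + wtp * (e - e0), ":", color="gray", label=f"WTP {wtp:,.0f}")
    ax.set_xlabel("DALYs averted vs no chemotherapy")
    ax.set_ylabel("lifetime cost (I$)")
    ax.legend(fontsize=8)
    return ax


def plot_tornado(dsa: pd.DataFrame, ax=None):
    """Horizontal-bar tornado of the headline ICER at each range end."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(dsa) + 1.5))
    base = dsa.attrs.get("base_icer", np.nan)
    dsa = dsa.iloc[::-1]
    y = np.arange(len(dsa))
    lo = np.minimum(dsa["icer_low"], dsa["icer_high"])
    hi = np.maximum(dsa["icer_low"], dsa["icer_high"])
    ax.barh(y, hi - lo, left=lo, color="tab:orange", alpha=0.8)
    if np.isfinite(base):
        ax.axvline(base, color="k", lw=1)
    ax.set_yticks(y, dsa["parameter"], fontsize=7)
    ax.set_xlabel("headline ICER (I$/DALY averted)")
    return ax


def plot_ceac(curves: pd.DataFrame, ax=None):
    """Probability each strategy is optimal across willingness-to-pay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for col in curves.columns:
        ax.plot(curves.index, curves[col], label=col)
    ax.set_xlabel("willingness to pay (I$/DALY averted)")
    ax.set_ylabel("probability optimal")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    return ax


def plot_psa_scatter(psa_samples: pd.DataFrame, comparator: str = "NO_CHEMO", ax=None):
    """Incremental cost vs incremental effect cloud per strategy."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    base = psa_samples[psa_samples["strategy"] == comparator].set_index("iteration")
    for name, sub in psa_samples.groupby("strategy"):
        if name == comparator:
            continue
        sub = sub.set_index("iteration")
        ax.scatter(
            sub["effect"] - base["effect"],
            sub["cost"] - base["cost"],
            s=4, alpha=0.35, label=name,
        )
    ax.set_xlabel("incremental DALYs averted")
    ax.set_ylabel("incremental cost (I$)")
    ax.legend(fontsize=7, markerscale=2)
    return ax
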