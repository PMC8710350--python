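"""Time-inhomogeneous Markov cohort engine.

The cohort starts disease-free at age 60 and is propagated month by
month over a 300-month horizon.  Within a cycle, competing exits
(recurrence vs background death from the disease-free state; cancer
death vs background death from recurrence states) are combined on the
rate scale: monthly probabilities are converted to rates
``r = -ln(1 - p)``, rates of competing exits are summed, the total exit
probability is ``1 - exp(-sum)`` and is apportioned by rate share.
This keeps every transition row stochastic even when the marginal
probabilities are large.

Any cohort fraction still alive at the final boundary (month 300, age
85) is moved to death from other causes, reflecting a life table that
reaches probability one at 85.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet, StrategySpec
from .states import STRATA, StateSpace, Stratum, build_state_space, stratum_of_month

ROW_SUM_TOL = 1e-9


class ConsistencyError(RuntimeError):
    """The engine produced a non-stochastic transition or trace row."""


@dataclass
class TransitionTensors:
    """Per-cycle transition structure.

    Every transient state has at most three exits:

    * ``p_stay``: remain/advance to ``t_stay`` (DF -> DF; tunnel k -> k+1,
      the deepest tunnel self-looping);
    * ``p_event``: the disease event to ``t_event`` (DF -> recurrence entry
      for the stratum of the current model month; recurrence -> cancer death);
    * ``p_other``: background death (always to ``death_other``).

    Shapes: ``p_*`` are ``(horizon, n_states)``; ``t_stay`` is ``(n_states,)``;
    ``t_event`` is ``(horizon, n_states)``.
    """

    space: StateSpace
    p_stay: np.ndarray
    p_event: np.ndarray
    p_other: np.ndarray
    t_stay: np.ndarray
    t_event: np.ndarray


def _rate(p: np.ndarray | float) -> np.ndarray | float:
    # p = 1 maps to an infinite rate; _split_exits resolves it to certain exit
    with np.errstate(divide="ignore"):
        return -np.log1p(-np.asarray(p, dtype=float))


def _split_exits(r_event, r_other):
    """Total-exit probability apportioned by rate share."""
    r_event = np.asarray(r_event, dtype=float)
    r_other = np.asarray(r_other, dtype=float)
    total = r_event + r_other
    p_exit = -np.expm1(-total)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, r_event / np.where(total > 0, total, 1.0), 0.0)
    return p_exit * share, p_exit * (1.0 - share)


def build_transition_tensors(
    strategy: StrategySpec, params: ParameterSet, space: StateSpace | None = None
) -> TransitionTensors:
    if space is None:
        space = build_state_space(params.tunnel_depth, params.horizon_months)
    H, S, D = params.horizon_months, None, space.tunnel_depth
    S = space.n_states

    p_stay = np.zeros((H, S))
    p_event = np.zeros((H, S))
    p_other = np.zeros((H, S))
    t_stay = np.arange(S)
    t_event = np.zeros((H, S), dtype=np.int64)

    months = np.arange(H)
    n_years = -(-H // 12)
    q_years = np.array(
        [params.annual_background(params.start_age + y) for y in range(n_years)]
    )
    p_bg = 1.0 - (1.0 - np.repeat(q_years, 12)[:H]) ** (1.0 / 12.0)
    r_bg = _rate(p_bg)

    # disease-free row
    p_rec = params.recurrence_cycle_probs(strategy.name)
    if np.any((p_rec < 0) | (p_rec > 1)):
        m = int(np.argmax((p_rec < 0) | (p_rec > 1)))
        raise ParameterErrorFor(strategy.name, m, p_rec[m])
    r_rec = _rate(p_rec)
    ev, ot = _split_exits(r_rec, r_bg)
    df = space.disease_free
    p_event[:, df] = ev
    p_other[:, df] = ot
    p_stay[:, df] = 1.0 - ev - ot
    entry_codes = np.array([space.recurrence(s, 0) for s in STRATA])
    t_event[:, df] = entry_codes[
        np.where(months <= 24, 0, np.where(months <= 36, 1, 2))
    ]

    # recurrence tunnels: cancer death depends on (stratum, months in state),
    # background death on age only; the deepest tunnel self-loops.
    d_grid = np.stack(
        [np.asarray(params.crc_death_prob[s.value], dtype=float) for s in STRATA]
    )  # (3, D)
    r_d = _rate(d_grid)[None, :, :]  # (1, 3, D)
    ev, ot = _split_exits(
        np.broadcast_to(r_d, (H, 3, D)), r_bg[:, None, None]
    )  # (H, 3, D)
    rec_codes = np.array(
        [[space.recurrence(s, k) for k in range(D)] for s in STRATA]
    )  # (3, D)
    flat = rec_codes.ravel()
    p_event[:, flat] = ev.reshape(H, -1)
    p_other[:, flat] = ot.reshape(H, -1)
    p_stay[:, flat] = 1.0 - p_event[:, flat] - p_other[:, flat]
    t_event[:, flat] = space.death_crc
    # advance: k -> min(k+1, D-1)
    nxt = np.minimum(np.arange(D) + 1, D - 1)
    t_stay[flat] = rec_codes[:, nxt].ravel()

    # absorbing states
    for a in space.absorbing:
        p_stay[:, a] = 1.0
        t_event[:, a] = a
    return TransitionTensors(space, p_stay, p_event, p_other, t_stay, t_event)


def ParameterErrorFor(strategy: str, month: int, value) -> Exception:
    from .parameters import ParameterError

    return ParameterError(
        f"recurrence_prob.{strategy}[{month}] = {value} outside [0, 1] after combination"
    )


def transition_row(
    state: int,
    model_month: int,
    params: ParameterSet,
    strategy: StrategySpec,
    space: StateSpace | None = None,
) -> np.ndarray:
    """Probability vector over all states for one transient-state transition.

    Scalar reference arithmetic, kept independent of the vectorized tensor
    builder so each can check the other.
    """
    if space is None:
        space = build_state_space(params.tunnel_depth, params.horizon_months)
    if not 0 <= model_month < params.horizon_months:
        raise ValueError(f"model_month {model_month} outside horizon")
    row = np.zeros(space.n_states)
    if state in space.absorbing:
        row[state] = 1.0
        return row
    r_bg = -np.log(1.0 - params.monthly_background(model_month))
    if state == space.disease_free:
        p = params.recurrence_probability(strategy.name, model_month)
        if not 0.0 <= p <= 1.0:
            raise ParameterErrorFor(strategy.name, model_month, p)
        r_ev = -np.log(1.0 - p)
        target = space.recurrence(stratum_of_month(model_month), 0)
    else:
        s, k = space.decode_recurrence(state)
        d = params.crc_death_probability(s, k)
        r_ev = -np.log(1.0 - d)
        target = space.death_crc
    total = r_ev + r_bg
    if total > 0:
        p_exit = 1.0 - np.exp(-total)
        row[target] += p_exit * r_ev / total
        row[space.death_other] += p_exit * r_bg / total
    if state == space.disease_free:
        row[space.disease_free] = 1.0 - row.sum()
    else:
        stay = space.recurrence(s, k + 1)
        row[stay] += 1.0 - row[target] - row[space.death_other]
    return row


@dataclass
class CohortTrace:
    """Per-cycle cohort occupancy and entry flux.

    ``occupancy[t, s]`` is the cohort fraction in state ``s`` at month
    boundary ``t`` (rows ``0..horizon``).  ``entry_flux[t, s]`` is the
    fraction newly arriving in ``s`` at boundary ``t`` from outside its
    own tunnel chain (needed for one-time costs such as hepatectomy on
    entering recurrence).
    """

    space: StateSpace
    strategy: str
    occupancy: np.ndarray
    entry_flux: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive_occupancy(self) -> np.ndarray:
        return self.occupancy[:, self.space.alive_codes].sum(axis=1)

    def disease_free_occupancy(self) -> np.ndarray:
        return self.occupancy[:, self.space.disease_free]

    def recurrence_occupancy(self, stratum: Stratum | None = None) -> np.ndarray:
        if stratum is None:
            codes = [c for c in self.space.alive_codes if self.space.is_recurrence(c)]
        else:
            codes = [self.space.recurrence(stratum, k) for k in range(self.space.tunnel_depth)]
        return self.occupancy[:, codes].sum(axis=1)

    def macro_occupancy(self) -> np.ndarray:
        """Occupancy collapsed to six macro states:
        DF, recurrence by stratum, death_crc, death_other; shape (H+1, 6)."""
        cols = [self.disease_free_occupancy()]
        cols += [self.recurrence_occupancy(s) for s in STRATA]
        cols += [
            self.occupancy[:, self.space.death_crc],
            self.occupancy[:, self.space.death_other],
        ]
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy, columns=self.space.labels,
            index=pd.RangeIndex(self.horizon + 1, name="cycle"),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def run_cohort(
    strategy: StrategySpec,
    params: ParameterSet,
    space: StateSpace | None = None,
    tensors: TransitionTensors | None = None,
) -> CohortTrace:
    """Deterministic cohort push-forward over the full horizon.

    The whole cohort starts disease-free; rows are checked to sum to one
    within ``1e-9``; alive mass remaining at the final boundary is forced
    to death from other causes.
    """
    if tensors is None:
        tensors = build_transition_tensors(strategy, params, space)
    space = tensors.space
    H, S, D = params.horizon_months, space.n_states, space.tunnel_depth
    occ = np.zeros((H + 1, S))
    flux = np.zeros((H + 1, S))
    occ[0, space.disease_free] = 1.0
    flux[0, space.disease_free] = 1.0

    # block views: recurrence codes 1..3D are contiguous, stratum-major
    dfc = space.disease_free
    rec_sl = slice(1, 1 + 3 * D)
    p0r = tensors.p_stay[:, rec_sl].reshape(H, 3, D)
    p1r = tensors.p_event[:, rec_sl].reshape(H, 3, D)
    p2r = tensors.p_other[:, rec_sl].reshape(H, 3, D)
    entry_row = (tensors.t_event[:, dfc] - 1) // D  # stratum index per month

    df = 1.0
    rec = np.zeros((3, D))
    dcrc = 0.0
    doth = 0.0
    for t in range(H):
        df_entry = df * tensors.p_event[t, dfc]
        crc_in = float((rec * p1r[t]).sum())
        oth_in = float((rec * p2r[t]).sum()) + df * tensors.p_other[t, dfc]
        new_rec = np.zeros((3, D))
        new_rec[:, 1:] = rec[:, :-1] * p0r[t, :, :-1]
        new_rec[:, -1] += rec[:, -1] * p0r[t, :, -1]  # deepest tunnel self-loops
        new_rec[entry_row[t], 0] += df_entry
        df = df * tensors.p_stay[t, dfc]
        dcrc += crc_in
        doth += oth_in
        rec = new_rec
        flux[t + 1, 1 + entry_row[t] * D] = df_entry
        flux[t + 1, space.death_crc] = crc_in
        flux[t + 1, space.death_other] = oth_in
        if t == H - 1:
            # terminal forcing: survivors at age 85 die of other causes,
            # cancelling any same-boundary recurrence entries
            leftover = df + float(rec.sum())
            flux[t + 1, 1 + entry_row[t] * D] = 0.0
            flux[t + 1, space.death_other] = oth_in + leftover
            doth += leftover
            df = 0.0
            rec[:] = 0.0
        occ[t + 1, dfc] = df
        occ[t + 1, rec_sl] = rec.ravel()
        occ[t + 1, space.death_crc] = dcrc
        occ[t + 1, space.death_other] = doth

    sums = occ.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
        t = int(np.argmax(np.abs(sums - 1.0)))
        raise ConsistencyError(
            f"trace row {t} sums to {sums[t]!r}, outside tolerance {ROW_SUM_TOL}"
        )
    return CohortTrace(space, strategy.name, occ, flux)


def half_cycle_weights(trace: CohortTrace) -> np.ndarray:
    """Trapezoidal per-cycle accrual weights: the mean of occupancy at the
    two cycle boundaries; shape ``(horizon, n_states)``."""
    occ = trace.occupancy
    return 0.5 * (occ[:-1] + occ[1:])


def overall_survival_years(trace: CohortTrace) -> float:
    """Undiscounted, disability-unadjusted life-years per patient."""
    w = half_cycle_weights(trace)
    return float(w[:, trace.space.alive_codes].sum() / 12.0)
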