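"""Kaplan-Meier digitization to monthly transition probabilities.

Digitized survival coordinates from trial disease-free / recurrence-free
curves are smoothed with a monotone spline on the log-survival scale,
converted to monthly event probabilities via the discrete hazard
``p(m) = (S(m) - S(m+1)) / S(m)``, extrapolated from the trial end to
the cure month (default: carry the last fitted monthly hazard forward),
and set to exactly zero after the cure month (patients disease-free for
more than 96 months are considered cured).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, UnivariateSpline

from .engine import CohortTrace
from .parameters import ParameterSet


class CurveValidationError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class KMCurve:
    """Digitized survival points for one strategy/endpoint."""

    times: np.ndarray
    survival: np.ndarray
    label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape or self.times.ndim != 1:
            raise CurveValidationError(f"{self.label}: times/survival shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise CurveValidationError(f"{self.label}: times must be strictly increasing")
        if self.times[0] != 0 or self.survival[0] != 1.0:
            raise CurveValidationError(f"{self.label}: curve must start at (0, 1)")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise CurveValidationError(f"{self.label}: survival outside [0, 1]")
        rising = np.flatnonzero(np.diff(self.survival) > 0)
        if rising.size:
            pairs = [
                (float(self.times[i]), float(self.times[i + 1])) for i in rising
            ]
            raise CurveValidationError(
                f"{self.label}: survival increases between time pairs {pairs}"
            )

    @classmethod
    def from_csv(cls, path, label: str = "", source: str = "") -> "KMCurve":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["survival"].to_numpy(),
                   label=label or str(path), source=source)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_months": self.times, "survival": self.survival}).to_csv(
            path, index=False
        )


@dataclass
class SurvivalFunction:
    """Continuous-time survival evaluator fitted to KM points.

    Internally a monotone interpolant over a monthly grid of spline
    values on the log-survival scale, isotonically projected so the
    result is non-increasing with S(0) = 1 and values in [0, 1].
    """

    grid: np.ndarray
    values: np.ndarray
    knots: np.ndarray
    extrapolation_boundary: float
    family: str = "pchip-log"
    _interp: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._interp = PchipInterpolator(self.grid, self.values, extrapolate=False)
        # beyond the boundary, continue at the hazard of the last month
        v = self.values
        self._tail_hazard = 0.0
        if len(v) >= 2 and v[-2] > 0 and v[-1] > 0:
            self._tail_hazard = -np.log(v[-1] / v[-2])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        inside = np.clip(t, self.grid[0], self.grid[-1])
        out = self._interp(inside)
        beyond = t > self.grid[-1]
        if np.any(beyond):
            out = np.where(
                beyond,
                self.values[-1] * np.exp(-self._tail_hazard * (t - self.grid[-1])),
                out,
            )
        out = np.clip(out, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


def fit_survival_spline(
    curve: KMCurve,
    smoothing: float | None = None,
    tolerance: float = 0.005,
) -> SurvivalFunction:
    """Fit a monotone spline to digitized KM points.

    By default a shape-preserving cubic (PCHIP) interpolates log-survival
    exactly; a positive ``smoothing`` switches to a smoothing spline with
    that smoothing factor.  The fitted values on the monthly grid are
    isotonically projected (running minimum) in case smoothing introduced
    a local increase, and the fit must pass within ``tolerance`` (default
    0.5 percentage points) of every input point.
    """
    if len(curve.times) < 4:
        raise FitError(f"{curve.label}: need at least 4 points, got {len(curve.times)}")
    pos = np.clip(curve.survival, 1e-12, 1.0)
    logs = np.log(pos)
    end = float(curve.times[-1])
    grid = np.arange(0.0, np.floor(end) + 1.0)
    if grid[-1] < end:
        grid = np.append(grid, end)
    if smoothing is None:
        raw = PchipInterpolator(curve.times, logs)(grid)
        family = "pchip-log"
    else:
        k = min(3, len(curve.times) - 1)
        spl = UnivariateSpline(curve.times, logs, k=k, s=smoothing)
        raw = spl(grid)
        family = f"smoothing-log(s={smoothing})"
    vals = np.minimum.accumulate(np.clip(np.exp(raw), 0.0, 1.0))
    vals[0] = 1.0
    fitted = SurvivalFunction(
        grid=grid, values=vals, knots=curve.times.copy(),
        extrapolation_boundary=end, family=family,
    )
    err = np.abs(fitted(curve.times) - curve.survival)
    if np.any(err > tolerance):
        i = int(np.argmax(err))
        raise FitError(
            f"{curve.label}: fitted curve misses point t={curve.times[i]} "
            f"by {err[i]:.4f} (> {tolerance})"
        )
    return fitted


def monthly_event_probability(S: SurvivalFunction, m: int) -> float:
    """Discrete monthly hazard ``(S(m) - S(m+1)) / S(m)``."""
    sm = float(S(m))
    if sm <= 0.0:
        raise ZeroDivisionError(f"survival is 0 at month {m}; hazard undefined")
    p = (sm - float(S(m + 1))) / sm
    return float(min(max(p, 0.0), 1.0))


def extrapolate_and_cure(
    S: SurvivalFunction,
    trial_end: int,
    cure_month: int = 96,
    horizon: int = 300,
    tail_rule: str = "carry_forward",
) -> pd.Series:
    """Monthly event-probability table indexed by model month 1..horizon.

    Months up to ``trial_end`` come from the fitted spline; months in
    ``(trial_end, cure_month]`` use the tail rule (``carry_forward``: the
    last fitted monthly hazard; ``exp_fit``: the mean hazard of the final
    24 fitted months); months beyond the cure month are exactly zero.
    """
    if trial_end > cure_month:
        raise ValueError("trial_end must be <= cure_month")
    months = np.arange(1, horizon + 1)
    probs = np.zeros(horizon)
    fitted = [monthly_event_probability(S, m - 1) for m in range(1, trial_end + 1)]
    probs[: trial_end] = fitted
    if tail_rule == "carry_forward":
        tail_p = fitted[-1] if fitted else 0.0
    elif tail_rule == "exp_fit":
        recent = fitted[-24:] if fitted else [0.0]
        haz = -np.log1p(-np.asarray(recent))
        tail_p = float(-np.expm1(-haz.mean()))
    else:
        raise ValueError(f"unknown tail rule {tail_rule!r}")
    probs[trial_end:cure_month] = tail_p
    return pd.Series(probs, index=pd.Index(months, name="month"), name="event_prob")


def monthly_table_to_cycle_probs(table: pd.Series, horizon: int) -> np.ndarray:
    """Convert a month-indexed table (month m = event in (m-1, m]) to the
    cycle-indexed array the engine consumes (entry t = cycle t -> t+1)."""
    arr = np.zeros(horizon)
    vals = table.reindex(range(1, horizon + 1), fill_value=0.0).to_numpy(float)
    arr[:] = vals
    return arr


def validate_against_trial(
    trace: CohortTrace,
    landmark: tuple[int, float],
    params: ParameterSet,
    mode: str = "recurrence_free",
) -> float:
    """Absolute deviation (percentage points) between the model's
    disease-free survival and a trial landmark.

    ``recurrence_free`` (default) renormalizes disease-free occupancy to
    exclude background (non-cancer) deaths, recovering the recurrence
    survival curve the model was calibrated to; ``all_death`` compares the
    raw disease-free occupancy, which counts background deaths as events.
    """
    month, trial_surv = landmark
    if not 0 <= month <= trace.horizon:
        raise ValueError("landmark month outside horizon")
    df_occ = float(trace.disease_free_occupancy()[month])
    if mode == "recurrence_free":
        r_bg = np.array([
            -np.log(1.0 - params.monthly_background(m)) for m in range(month)
        ])
        model = df_occ / float(np.exp(-r_bg.sum()))
    elif mode == "all_death":
        model = df_occ
    else:
        raise ValueError(f"unknown DFS mode {mode!r}")
    return abs(model - trial_surv) * 100.0
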