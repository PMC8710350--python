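"""Health-state space for the colon-cancer cohort model.

The model tracks a cohort of surgically resected stage III colon cancer
patients through four conceptual states: disease-free, distant recurrence,
death from colon cancer, and death from other causes.  Recurrence is
stratified by *when* it occurred relative to surgery (early: within 2
years; mid: years 2-3; late: after year 3) and expanded into tunnel
states by months already spent in recurrence, so that post-recurrence
mortality can depend on both.

State layout (integer codes):

    0                          disease_free
    1 .. 3*depth               recurrence tunnels, stratum-major
    3*depth + 1                death_crc      (absorbing)
    3*depth + 2                death_other    (absorbing)
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Stratum(str, Enum):
    """Timing of recurrence relative to surgery."""

    EARLY = "early"  # recurrence in model months 0-24
    MID = "mid"      # months 25-36
    LATE = "late"    # months > 36


STRATA: tuple[Stratum, ...] = (Stratum.EARLY, Stratum.MID, Stratum.LATE)


def stratum_of_month(month: int) -> Stratum:
    """Stratum a recurrence belongs to when it occurs at ``month``.

    Boundary months go to the earlier stratum (24 -> early, 36 -> mid).
    """
    if month <= 24:
        return Stratum.EARLY
    if month <= 36:
        return Stratum.MID
    return Stratum.LATE


@dataclass(frozen=True)
class StateSpace:
    """Expanded tunnel-state enumeration.

    Parameters
    ----------
    tunnel_depth : int
        Number of months-in-recurrence tunnel states per stratum.  The
        deepest tunnel state self-loops: mortality lookups beyond the
        cap reuse the deepest available index.
    horizon : int
        Model horizon in months (used only for validation/metadata).
    """

    tunnel_depth: int
    horizon: int

    @property
    def n_states(self) -> int:
        return 3 * self.tunnel_depth + 3

    @property
    def disease_free(self) -> int:
        return 0

    @property
    def death_crc(self) -> int:
        return 3 * self.tunnel_depth + 1

    @property
    def death_other(self) -> int:
        return 3 * self.tunnel_depth + 2

    @property
    def absorbing(self) -> tuple[int, int]:
        return (self.death_crc, self.death_other)

    def recurrence(self, stratum: Stratum, months_in_recurrence: int) -> int:
        """Code of the tunnel state (capped at the tunnel depth)."""
        k = min(months_in_recurrence, self.tunnel_depth - 1)
        if k < 0:
            raise ValueError("months_in_recurrence must be >= 0")
        return 1 + STRATA.index(stratum) * self.tunnel_depth + k

    def is_recurrence(self, code: int) -> bool:
        return 1 <= code <= 3 * self.tunnel_depth

    def decode_recurrence(self, code: int) -> tuple[Stratum, int]:
        if not self.is_recurrence(code):
            raise ValueError(f"state {code} is not a recurrence state")
        idx = code - 1
        return STRATA[idx // self.tunnel_depth], idx % self.tunnel_depth

    @property
    def alive_codes(self) -> list[int]:
        return list(range(0, 3 * self.tunnel_depth + 1))

    @property
    def labels(self) -> list[str]:
        out = ["disease_free"]
        for s in STRATA:
            out += [f"rec_{s.value}_m{k:02d}" for k in range(self.tunnel_depth)]
        out += ["death_crc", "death_other"]
        return out


def build_state_space(tunnel_depth: int, horizon: int) -> StateSpace:
    """Build the expanded state enumeration.

    Raises
    ------
    ValueError
        If ``tunnel_depth`` or ``horizon`` is not a positive integer.
    """
    if tunnel_depth < 1:
        raise ValueError(f"tunnel_depth must be >= 1, got {tunnel_depth}")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    return StateSpace(tunnel_depth=int(tunnel_depth), horizon=int(horizon))
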