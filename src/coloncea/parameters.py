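"""Parameter container for the cohort model.

A :class:`ParameterSet` holds every numeric input: monthly recurrence
probabilities per strategy, post-recurrence monthly death probabilities
by recurrence stratum and months in recurrence, an age-indexed life
table, cost schedules, disability weights, the discount rate and the
willingness-to-pay threshold, plus optional per-entry PSA distribution
specifications.

Entries are addressable by dotted path (``"costs.CAPOX_3MO.drug_monthly"``)
for the deterministic and probabilistic sensitivity analyses.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

from .states import STRATA, Stratum

STRATEGY_NAMES = (
    "FOLFOX_3MO",
    "FOLFOX_6MO",
    "CAPOX_3MO",
    "CAPOX_6MO",
    "CAPECITABINE_6MO",
    "FULV_6MO",
    "NO_CHEMO",
)

OXALIPLATIN_STRATEGIES = ("FOLFOX_3MO", "FOLFOX_6MO", "CAPOX_3MO", "CAPOX_6MO")

COMPARATOR = "NO_CHEMO"

#: 2020 purchasing-power-parity conversion: ZAR per international dollar.
ZAR_PER_INTL = 6.86

#: Base-case willingness to pay (2020 South African GDP per capita, I$/DALY averted).
WTP_BASE = 13_006.56
WTP_LOW = 6_503.29
WTP_HIGH = 39_019.72

SCHEMA_VERSION = 1


class ParameterError(ValueError):
    """A model input violates its constraints; the message names the entry."""


@dataclass
class TraeEvent:
    """One treatment-related adverse event: probability per course/line,
    unit cost (I$), disability weight, and duration in months."""

    name: str
    probability: float
    cost: float
    disability_weight: float
    duration_months: float

    def expected_cost(self) -> float:
        return self.probability * self.cost

    def expected_disability_months(self) -> float:
        return self.probability * self.disability_weight * self.duration_months


@dataclass
class StrategySpec:
    """A treatment arm: regimen identity, duration and visit burden."""

    name: str
    adjuvant_duration_months: int
    n_treatment_visits: int
    is_infusional: bool = False

    def __post_init__(self) -> None:
        if self.adjuvant_duration_months not in (0, 3, 6):
            raise ParameterError(
                f"strategies.{self.name}.adjuvant_duration_months must be 0, 3 or 6"
            )
        if self.name == COMPARATOR and (
            self.adjuvant_duration_months != 0 or self.n_treatment_visits != 0
        ):
            raise ParameterError("NO_CHEMO must have zero duration and zero visits")


@dataclass
class StrategyCosts:
    """Adjuvant cost components per strategy, I$.

    Monthly components accrue every treatment month; the administration
    component (port-a-cath placement and infusion pumps for infusional
    regimens) is a per-course total spread over the treatment months.
    """

    drug_monthly: float = 0.0
    personnel_monthly: float = 0.0
    admin_course_total: float = 0.0
    antiemetics_monthly: float = 0.0
    bloodwork_monthly: float = 0.0

    def monthly_total(self, duration_months: int) -> float:
        base = (
            self.drug_monthly
            + self.personnel_monthly
            + self.antiemetics_monthly
            + self.bloodwork_monthly
        )
        if duration_months > 0:
            base += self.admin_course_total / duration_months
        return base


@dataclass
class IndirectCosts:
    """Societal indirect costs: transport and lost wages per visit,
    accrued for the patient and one caregiver."""

    transport_round_trip: float = 6.03
    hourly_wage: float = 2.52
    hours_per_visit: float = 8.0
    persons: int = 2

    def per_visit(self) -> float:
        return (
            self.transport_round_trip + self.hours_per_visit * self.hourly_wage
        ) * self.persons


@dataclass
class MetastaticCare:
    """Post-recurrence treatment pathway: at most two chemotherapy lines,
    then best supportive care; no biologic agents."""

    line1_months: int = 6
    line2_months: int = 6
    line1_monthly_cost: float = 800.0
    line2_monthly_cost: float = 600.0
    bsc_monthly_cost: float = 150.0
    visits_per_month_on_treatment: float = 1.0
    visits_per_month_bsc: float = 0.25
    trae_line1: list[TraeEvent] = field(default_factory=list)
    trae_line2: list[TraeEvent] = field(default_factory=list)


@dataclass
class DistributionSpec:
    """PSA distribution for one parameter entry.

    Families: ``beta`` (probabilities/weights) and ``gamma`` (costs),
    parameterised by the base-case mean and a coefficient of variation;
    ``lognormal`` (multiplicative hazard factors, mean 1, spread sigma);
    ``uniform`` (low/high); ``fixed`` (degenerate at the base value).
    """

    family: str
    mean: float | None = None
    cv: float = 0.2
    sigma: float = 0.1
    low: float | None = None
    high: float | None = None

    _MAX_REDRAWS = 100

    def sample(self, rng: np.random.Generator, base: float) -> float:
        mean = self.mean if self.mean is not None else base
        if self.family == "fixed" or (self.family in ("beta", "gamma") and self.cv == 0.0):
            return base
        if self.family == "beta":
            if not 0.0 < mean < 1.0:
                return base
            var = (self.cv * mean) ** 2
            nu = mean * (1.0 - mean) / var - 1.0
            if nu <= 0:
                raise ParameterError(
                    f"beta distribution with mean {mean} and cv {self.cv} is infeasible"
                )
            for _ in range(self._MAX_REDRAWS):
                x = rng.beta(mean * nu, (1.0 - mean) * nu)
                if 0.0 <= x <= 1.0:
                    return float(x)
            raise ParameterError("beta redraw limit exceeded")
        if self.family == "gamma":
            if mean <= 0:
                return base
            shape = 1.0 / self.cv**2
            return float(rng.gamma(shape, mean / shape))
        if self.family == "lognormal":
            if self.sigma == 0.0:
                return base
            # mean-1 multiplier: mu = -sigma^2/2
            return float(rng.lognormal(-0.5 * self.sigma**2, self.sigma))
        if self.family == "uniform":
            lo = self.low if self.low is not None else base * 0.8
            hi = self.high if self.high is not None else base * 1.2
            return float(rng.uniform(lo, hi))
        raise ParameterError(f"unknown PSA distribution family {self.family!r}")


@dataclass
class ParameterSet:
    """Every numeric input to the model.  See module docstring."""

    start_age: int = 60
    horizon_months: int = 300
    cycle_months: int = 1
    cure_month: int = 96
    discount_rate_annual: float = 0.05
    tunnel_depth: int = 60
    liver_only_fraction: float = 1.0 / 3.0
    hepatectomy_fraction_of_liver_only: float = 1.0 / 3.0
    wtp: float = WTP_BASE

    #: age (years) -> annual probability of death from causes other than
    #: colon cancer; must cover start_age..85 with value 1.0 at 85.
    background_mortality: dict[int, float] = field(default_factory=dict)

    #: strategy -> array of length horizon_months; entry m is the monthly
    #: recurrence probability applied during cycle m (model month m -> m+1).
    recurrence_prob: dict[str, np.ndarray] = field(default_factory=dict)

    #: strategy -> multiplicative hazard factor on recurrence (PSA/DSA/scenarios).
    recurrence_multiplier: dict[str, float] = field(default_factory=dict)

    #: stratum value -> array of length tunnel_depth: monthly probability of
    #: colon-cancer death by months already spent in recurrence.
    crc_death_prob: dict[str, np.ndarray] = field(default_factory=dict)

    strategies: dict[str, StrategySpec] = field(default_factory=dict)
    costs: dict[str, StrategyCosts] = field(default_factory=dict)
    trae_adjuvant: dict[str, list[TraeEvent]] = field(default_factory=dict)

    surveillance_monthly_cost: float = 40.0
    surveillance_visits_per_month: float = 1.0 / 3.0
    metastatic: MetastaticCare = field(default_factory=MetastaticCare)
    hepatectomy_cost: float = 6000.0
    hepatectomy_disability_weight: float = 0.3
    hepatectomy_disability_months: float = 1.0
    indirect: IndirectCosts = field(default_factory=IndirectCosts)

    #: state label -> disability weight in [0, 1] (1 = death from colon cancer).
    disability_weights: dict[str, float] = field(
        default_factory=lambda: {
            "disease_free": 0.0,
            "recurrence": 0.45,
            "death_crc": 1.0,
            "death_other": 0.0,
        }
    )

    #: dotted parameter path -> DistributionSpec (entries varied in the PSA).
    psa_distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    schema_version: int = SCHEMA_VERSION

    # ------------------------------------------------------------------ lookups

    def strategy_names(self) -> list[str]:
        return list(self.strategies)

    def recurrence_probability(self, strategy: str, month: int) -> float:
        """Monthly recurrence probability applied during cycle ``month``,
        with the strategy's hazard multiplier and the cure rule applied."""
        if month >= self.cure_month:
            return 0.0
        p = float(self.recurrence_prob[strategy][month])
        m = self.recurrence_multiplier.get(strategy, 1.0)
        if m != 1.0:
            p = 1.0 - (1.0 - p) ** m
        return p

    def recurrence_cycle_probs(self, strategy: str) -> np.ndarray:
        """Vector of monthly recurrence probabilities over all cycles."""
        p = np.asarray(self.recurrence_prob[strategy], dtype=float).copy()
        m = self.recurrence_multiplier.get(strategy, 1.0)
        if m != 1.0:
            p = 1.0 - (1.0 - p) ** m
        p[self.cure_month:] = 0.0
        return p

    def annual_background(self, age: int) -> float:
        return float(self.background_mortality[min(int(age), 85)])

    def monthly_background(self, month: int) -> float:
        """Monthly probability of non-cancer death during cycle ``month``
        (constant hazard within each life-table year)."""
        age = self.start_age + month // 12
        return 1.0 - (1.0 - self.annual_background(age)) ** (1.0 / 12.0)

    def crc_death_probability(self, stratum: Stratum, months_in_recurrence: int) -> float:
        k = min(int(months_in_recurrence), self.tunnel_depth - 1)
        return float(self.crc_death_prob[stratum.value][k])

    # --------------------------------------------------------------- validation

    def validate(self) -> None:
        """Check every invariant; raise :class:`ParameterError` naming the
        offending entry."""
        if self.horizon_months != 12 * (85 - self.start_age):
            raise ParameterError(
                "horizon_months must equal 12*(85 - start_age): "
                f"got {self.horizon_months} for start_age {self.start_age}"
            )
        if not 0.0 <= self.discount_rate_annual:
            raise ParameterError("discount_rate_annual must be >= 0")
        if self.tunnel_depth < 1:
            raise ParameterError("tunnel_depth must be >= 1")
        for frac_name in ("liver_only_fraction", "hepatectomy_fraction_of_liver_only"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{frac_name} must be in [0, 1], got {v}")

        ages = range(self.start_age, 86)
        for a in ages:
            if a not in self.background_mortality:
                raise ParameterError(f"background_mortality missing age {a}")
            q = self.background_mortality[a]
            if not 0.0 <= q <= 1.0:
                raise ParameterError(f"background_mortality.{a} = {q} outside [0, 1]")
        if self.background_mortality[85] != 1.0:
            raise ParameterError("background_mortality.85 must be exactly 1.0")

        if COMPARATOR not in self.strategies:
            raise ParameterError(f"strategies must include the comparator {COMPARATOR}")
        for name, spec in self.strategies.items():
            if name not in self.recurrence_prob:
                raise ParameterError(f"recurrence_prob missing strategy {name}")
            p = np.asarray(self.recurrence_prob[name], dtype=float)
            if p.shape != (self.horizon_months,):
                raise ParameterError(
                    f"recurrence_prob.{name} must have length {self.horizon_months}"
                )
            if np.any((p < 0) | (p > 1)):
                m = int(np.argmax((p < 0) | (p > 1)))
                raise ParameterError(
                    f"recurrence_prob.{name}[{m}] = {p[m]} outside [0, 1]"
                )
            if np.any(p[self.cure_month:] != 0.0):
                m = self.cure_month + int(np.argmax(p[self.cure_month:] != 0.0))
                raise ParameterError(
                    f"recurrence_prob.{name}[{m}] nonzero beyond cure_month"
                )
            mult = self.recurrence_multiplier.get(name, 1.0)
            if mult <= 0:
                raise ParameterError(f"recurrence_multiplier.{name} must be > 0")
            if name == COMPARATOR:
                continue
            if name not in self.costs:
                raise ParameterError(f"costs missing strategy {name}")
            if name not in self.trae_adjuvant:
                raise ParameterError(f"trae_adjuvant missing strategy {name}")

        if COMPARATOR in self.trae_adjuvant:
            for ev in self.trae_adjuvant[COMPARATOR]:
                if ev.probability != 0.0:
                    raise ParameterError("NO_CHEMO adjuvant TRAE probabilities must be 0")
        if COMPARATOR in self.costs:
            c = self.costs[COMPARATOR]
            if c.monthly_total(1) != 0.0:
                raise ParameterError("NO_CHEMO adjuvant costs must be 0")

        for s in STRATA:
            if s.value not in self.crc_death_prob:
                raise ParameterError(f"crc_death_prob missing stratum {s.value}")
            d = np.asarray(self.crc_death_prob[s.value], dtype=float)
            if d.shape != (self.tunnel_depth,):
                raise ParameterError(
                    f"crc_death_prob.{s.value} must have length {self.tunnel_depth}"
                )
            if np.any((d < 0) | (d > 1)):
                k = int(np.argmax((d < 0) | (d > 1)))
                raise ParameterError(
                    f"crc_death_prob.{s.value}[{k}] = {d[k]} outside [0, 1]"
                )

        for key, w in self.disability_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ParameterError(f"disability_weights.{key} = {w} outside [0, 1]")
        if not 0.0 <= self.hepatectomy_disability_weight <= 1.0:
            raise ParameterError("hepatectomy_disability_weight outside [0, 1]")

        for owner, events in self._iter_trae():
            for i, ev in enumerate(events):
                if not 0.0 <= ev.probability <= 1.0:
                    raise ParameterError(f"{owner}.{i}.probability outside [0, 1]")
                if not 0.0 <= ev.disability_weight <= 1.0:
                    raise ParameterError(f"{owner}.{i}.disability_weight outside [0, 1]")
                if ev.cost < 0:
                    raise ParameterError(f"{owner}.{i}.cost must be >= 0")

        for name, c in self.costs.items():
            for f in dataclasses.fields(c):
                if getattr(c, f.name) < 0:
                    raise ParameterError(f"costs.{name}.{f.name} must be >= 0")
        for f in ("surveillance_monthly_cost", "hepatectomy_cost"):
            if getattr(self, f) < 0:
                raise ParameterError(f"{f} must be >= 0")
        met = self.metastatic
        for f in ("line1_monthly_cost", "line2_monthly_cost", "bsc_monthly_cost"):
            if getattr(met, f) < 0:
                raise ParameterError(f"metastatic.{f} must be >= 0")

    def _iter_trae(self) -> Iterator[tuple[str, list[TraeEvent]]]:
        for name, events in self.trae_adjuvant.items():
            yield f"trae_adjuvant.{name}", events
        yield "metastatic.trae_line1", self.metastatic.trae_line1
        yield "metastatic.trae_line2", self.metastatic.trae_line2

    # ------------------------------------------------------------ path access

    def get_path(self, path: str) -> Any:
        obj: Any = self
        for part in path.split("."):
            obj = _step(obj, part)
        return obj

    def set_path(self, path: str, value: Any) -> None:
        parts = path.split(".")
        obj: Any = self
        for part in parts[:-1]:
            obj = _step(obj, part)
        last = parts[-1]
        if isinstance(obj, dict):
            key = last if last in obj else _coerce_key(obj, last)
            obj[key] = value
        elif isinstance(obj, (list, np.ndarray)):
            obj[int(last)] = value
        else:
            if not hasattr(obj, last):
                raise ParameterError(f"unknown parameter path {path!r}")
            setattr(obj, last, value)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def content_hash(self) -> str:
        """Stable hash of the numeric content, for run provenance logs."""
        payload = json.dumps(to_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # ---------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        return to_jsonable(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return _parameter_set_from_dict(d)


def _step(obj: Any, part: str) -> Any:
    if isinstance(obj, dict):
        if part in obj:
            return obj[part]
        return obj[_coerce_key(obj, part)]
    if isinstance(obj, (list, np.ndarray)):
        return obj[int(part)]
    if hasattr(obj, part):
        return getattr(obj, part)
    raise ParameterError(f"unknown parameter path component {part!r}")


def _coerce_key(d: dict, part: str) -> Any:
    for k in d:
        if str(k) == part:
            return k
    try:
        ik = int(part)
    except ValueError:
        raise ParameterError(f"unknown key {part!r}") from None
    if ik in d:
        return ik
    raise ParameterError(f"unknown key {part!r}")


# ------------------------------------------------------------------ (de)serialization helpers


def to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [float(x) for x in obj]
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _trae_list(raw: list[dict]) -> list[TraeEvent]:
    return [TraeEvent(**ev) for ev in raw]


def _parameter_set_from_dict(d: dict) -> ParameterSet:
    d = copy.deepcopy(d)
    version = d.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ParameterError(f"unrecognized schema_version {version}")
    d["background_mortality"] = {
        int(k): float(v) for k, v in d.get("background_mortality", {}).items()
    }
    d["recurrence_prob"] = {
        k: np.asarray(v, dtype=float) for k, v in d.get("recurrence_prob", {}).items()
    }
    d["crc_death_prob"] = {
        k: np.asarray(v, dtype=float) for k, v in d.get("crc_death_prob", {}).items()
    }
    d["strategies"] = {k: StrategySpec(**v) for k, v in d.get("strategies", {}).items()}
    d["costs"] = {k: StrategyCosts(**v) for k, v in d.get("costs", {}).items()}
    d["trae_adjuvant"] = {
        k: _trae_list(v) for k, v in d.get("trae_adjuvant", {}).items()
    }
    met = d.get("metastatic", {})
    met["trae_line1"] = _trae_list(met.get("trae_line1", []))
    met["trae_line2"] = _trae_list(met.get("trae_line2", []))
    d["metastatic"] = MetastaticCare(**met)
    d["indirect"] = IndirectCosts(**d.get("indirect", {}))
    d["psa_distributions"] = {
        k: DistributionSpec(**v) for k, v in d.get("psa_distributions", {}).items()
    }
    return ParameterSet(schema_version=version, **d)
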