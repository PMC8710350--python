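"""Configuration loading/validation and file readers/writers.

Run configuration is YAML with a versioned schema.  Model inputs come
either from a serialized ParameterSet (``parameters_file``), from the
synthetic generator (``synthetic:`` block), or both (files override the
generated baseline); digitized KM curves (``km_files``) are calibrated
into monthly recurrence probabilities at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .calibration import (
    KMCurve,
    extrapolate_and_cure,
    fit_survival_spline,
    monthly_table_to_cycle_probs,
)
from .parameters import SCHEMA_VERSION, ParameterError, ParameterSet

log = logging.getLogger("coloncea")

SCENARIOS = ("base", "low_risk", "high_risk")

#: strategies retained in the risk-stratified scenarios: the four
#: oxaliplatin-based arms plus the comparator.
RISK_SCENARIO_STRATEGIES = [
    "FOLFOX_3MO", "FOLFOX_6MO", "CAPOX_3MO", "CAPOX_6MO", "NO_CHEMO",
]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Resolved run settings (paths relative to the config file)."""

    path: Path
    seed: int = 0
    scenario: str = "base"
    wtp: float | None = None
    strategies: list[str] = field(default_factory=list)
    parameters_file: Path | None = None
    life_table_file: Path | None = None
    km_files: dict[str, Path] = field(default_factory=dict)
    trial_end_months: int = 60
    tail_rule: str = "carry_forward"
    synthetic: dict = field(default_factory=dict)
    psa_n: int = 1000
    dsa_ranges: list[dict] = field(default_factory=list)
    output_dir: Path = Path("out")
    verbose: bool = False


def load_and_validate_config(path) -> tuple[RunConfig, ParameterSet]:
    """Read a YAML run config, resolve its inputs into a validated
    ParameterSet, and return both.  Errors name the offending field."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(f"{path}: schema_version must be {SCHEMA_VERSION}, got {version}")
    scenario = raw.get("scenario", "base")
    if scenario not in SCENARIOS:
        raise ConfigError(f"{path}: scenario must be one of {SCENARIOS}, got {scenario!r}")

    base = path.parent
    cfg = RunConfig(
        path=path,
        seed=int(raw.get("seed", 0)),
        scenario=scenario,
        wtp=raw.get("wtp"),
        strategies=list(raw.get("strategies", [])),
        parameters_file=_opt_path(base, raw.get("parameters_file"), "parameters_file"),
        life_table_file=_opt_path(base, raw.get("life_table_file"), "life_table_file"),
        km_files={
            k: _opt_path(base, v, f"km_files.{k}")
            for k, v in (raw.get("km_files") or {}).items()
        },
        trial_end_months=int(raw.get("trial_end_months", 60)),
        tail_rule=raw.get("tail_rule", "carry_forward"),
        synthetic=raw.get("synthetic") or {},
        psa_n=int((raw.get("psa") or {}).get("n", 1000)),
        dsa_ranges=list(raw.get("dsa") or []),
        output_dir=base / raw.get("output_dir", "out"),
        verbose=bool(raw.get("verbose", False)),
    )

    if cfg.parameters_file is not None:
        params = load_parameters(cfg.parameters_file)
    else:
        from .synthetic import SyntheticScenario, generate_parameter_set

        scen_kwargs = dict(cfg.synthetic)
        scen_kwargs.setdefault("seed", cfg.seed)
        risk = cfg.scenario if cfg.scenario in ("low_risk", "high_risk") else "base"
        params = generate_parameter_set(SyntheticScenario(**scen_kwargs), risk=risk)

    if cfg.life_table_file is not None:
        params.background_mortality = read_life_table(cfg.life_table_file)
    for strategy, km_path in cfg.km_files.items():
        if strategy not in params.strategies:
            raise ConfigError(f"{path}: km_files names unknown strategy {strategy!r}")
        curve = KMCurve.from_csv(km_path, label=strategy)
        S = fit_survival_spline(curve)
        table = extrapolate_and_cure(
            S, trial_end=cfg.trial_end_months, cure_month=params.cure_month,
            horizon=params.horizon_months, tail_rule=cfg.tail_rule,
        )
        params.recurrence_prob[strategy] = monthly_table_to_cycle_probs(
            table, params.horizon_months
        )
    if cfg.wtp is not None:
        params.wtp = float(cfg.wtp)
    for name in cfg.strategies:
        if name not in params.strategies:
            raise ConfigError(f"{path}: strategies lists unknown strategy {name!r}")
    try:
        params.validate()
    except ParameterError as e:
        raise ConfigError(f"{path}: {e}") from e
    log.info("loaded config %s (parameters %s)", path, params.content_hash())
    return cfg, params


def _opt_path(base: Path, value, fieldname: str) -> Path | None:
    if value is None:
        return None
    p = Path(value)
    if not p.is_absolute():
        p = base / p
    if not p.exists():
        raise ConfigError(f"{fieldname}: file not found: {p}")
    return p


# ------------------------------------------------------------------ tables


def read_life_table(path) -> dict[int, float]:
    df = pd.read_csv(path)
    return {int(a): float(q) for a, q in zip(df["age"], df["annual_probability"])}


def write_life_table(table: dict[int, float], path) -> None:
    pd.DataFrame(
        {"age": sorted(table), "annual_probability": [table[a] for a in sorted(table)]}
    ).to_csv(path, index=False)


def load_parameters(path) -> ParameterSet:
    raw = yaml.safe_load(Path(path).read_text())
    try:
        params = ParameterSet.from_dict(raw)
        params.validate()
    except (ParameterError, TypeError, KeyError) as e:
        raise ConfigError(f"{path}: {e}") from e
    return params


def save_parameters(params: ParameterSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


# ------------------------------------------------------------------ scenarios


def run_scenario(cfg: RunConfig, params: ParameterSet, scenario: str | None = None):
    """Full pipeline for one scenario; risk scenarios are restricted to the
    oxaliplatin-based arms plus the comparator."""
    from .model import MarkovCEA

    scenario = scenario or cfg.scenario
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}")
    if scenario in ("low_risk", "high_risk"):
        if cfg.parameters_file is None:
            from .synthetic import SyntheticScenario, generate_parameter_set

            scen_kwargs = dict(cfg.synthetic)
            scen_kwargs.setdefault("seed", cfg.seed)
            params = generate_parameter_set(SyntheticScenario(**scen_kwargs), risk=scenario)
        strategies = [s for s in RISK_SCENARIO_STRATEGIES if s in params.strategies]
        if len(strategies) < len(RISK_SCENARIO_STRATEGIES):
            missing = set(RISK_SCENARIO_STRATEGIES) - set(strategies)
            raise ConfigError(f"risk scenario missing strategies {sorted(missing)}")
    else:
        strategies = cfg.strategies or None
    model = MarkovCEA(params, strategies=strategies, wtp=cfg.wtp)
    return model.fit()
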