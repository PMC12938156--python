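"""Scenario configuration, validation, serialization, and the end-to-end
pipeline from a config to the incremental cost-effectiveness table.

A scenario is one human-editable YAML (or JSON) document: strategies (a
regimen preset or inline definition plus PFS/OS curves, inline-parametric,
inline-step, or a digitized-curve CSV path), utilities, horizon, discount
rate, willingness-to-pay threshold, and metadata such as the dMMR/pMMR
prevalence split.  Money is in whole 2024 USD; times are in years.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import regimens as _regimens
from .engine import CEAResult, Strategy, UtilitySet, run_cea
from .regimens import DosePhase, Regimen, ToxicityProfile
from .survival import SurvivalCurve, read_curve_csv, write_curve_csv

logger = logging.getLogger("psmcea")

__all__ = [
    "ScenarioConfig",
    "ScenarioValidationError",
    "load_scenario",
    "save_scenario",
    "run_pipeline",
    "scenario_hash",
]


class ScenarioValidationError(ValueError):
    """A scenario field failed validation; ``key`` names the offender."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


@dataclass
class ScenarioConfig:
    name: str
    strategies: List[Strategy]
    comparator: str
    utilities: UtilitySet = field(default_factory=UtilitySet)
    horizon: float = 5.0
    discount_rate: float = 0.0
    wtp: float = 100000.0
    mmr_split: Dict[str, float] = field(default_factory=lambda: {"dmmr": 0.33, "pmmr": 0.67})
    seed: Optional[int] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.horizon <= 0:
            raise ScenarioValidationError("horizon", f"must be positive, got {self.horizon}")
        if self.discount_rate < 0:
            raise ScenarioValidationError("discount_rate", "must be non-negative")
        if self.wtp < 0:
            raise ScenarioValidationError("wtp", "must be non-negative")
        names = [s.name for s in self.strategies]
        if len(names) != len(set(names)):
            raise ScenarioValidationError("strategies", f"duplicate strategy names in {names}")
        if len(names) < 1:
            raise ScenarioValidationError("strategies", "at least one strategy required")
        if self.comparator not in names:
            raise ScenarioValidationError(
                "comparator", f"{self.comparator!r} not among strategies {names}")

    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)


# -- (de)serialization -------------------------------------------------

def _curve_to_dict(curve: SurvivalCurve, curve_dir: Optional[str], stem: str):
    if curve.kind != "step":
        d = {"kind": curve.kind, "rate": float(curve.rate)}
        if curve.kind == "weibull":
            d["shape"] = float(curve.shape)
        return d
    if curve_dir is not None:
        fname = f"{stem}.csv"
        write_curve_csv(curve, os.path.join(curve_dir, fname))
        return {"kind": "step", "csv": fname, "extrapolation": curve.extrapolation}
    return {"kind": "step", "times": [round(float(t), 10) for t in curve.times],
            "probs": [round(float(p), 10) for p in curve.probs],
            "extrapolation": curve.extrapolation}


def _curve_from_dict(d: dict, base_dir: str, key: str) -> SurvivalCurve:
    try:
        kind = d["kind"]
        if kind == "step":
            if "csv" in d:
                path = d["csv"]
                if not os.path.isabs(path):
                    path = os.path.join(base_dir, path)
                if not os.path.exists(path):
                    raise ScenarioValidationError(key, f"curve file not found: {path}")
                return read_curve_csv(path, extrapolation=d.get("extrapolation", "hold"))
            return SurvivalCurve.step(d["times"], d["probs"],
                                      extrapolation=d.get("extrapolation", "hold"))
        if kind == "exponential":
            return SurvivalCurve.exponential(rate=d["rate"])
        if kind == "weibull":
            return SurvivalCurve.weibull(rate=d["rate"], shape=d.get("shape", 1.0))
        raise ScenarioValidationError(key, f"unknown curve kind {kind!r}")
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ScenarioValidationError):
            raise
        raise ScenarioValidationError(key, f"invalid curve specification: {exc}") from exc


def _regimen_to_dict(reg: Regimen):
    d = asdict(reg)
    return d


def _regimen_from_dict(d, key: str) -> Regimen:
    if isinstance(d, str):
        if d not in _regimens.REGIMEN_PRESETS:
            raise ScenarioValidationError(
                key, f"unknown regimen preset {d!r}; known: {sorted(_regimens.REGIMEN_PRESETS)}")
        return _regimens.REGIMEN_PRESETS[d]()
    try:
        def phase(p):
            return None if p is None else DosePhase(**p)
        return Regimen(
            name=d["name"],
            induction=phase(d["induction"]),
            maintenance=phase(d.get("maintenance")),
            toxicity=ToxicityProfile(**d["toxicity"]),
            guaranteed_doses=d.get("guaranteed_doses", 3),
            max_treatment_years=d.get("max_treatment_years"),
            immuno_price=d.get("immuno_price", 0.0),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ScenarioValidationError(key, f"invalid regimen: {exc}") from exc


def scenario_to_dict(config: ScenarioConfig, curve_dir: Optional[str] = None) -> dict:
    return {
        "name": config.name,
        "comparator": config.comparator,
        "horizon": config.horizon,
        "discount_rate": config.discount_rate,
        "wtp": config.wtp,
        "mmr_split": dict(config.mmr_split),
        "seed": config.seed,
        "metadata": dict(config.metadata),
        "utilities": {"on_treatment": config.utilities.on_treatment,
                      "progressive": config.utilities.progressive},
        "strategies": [
            {
                "name": s.name,
                "regimen": _regimen_to_dict(s.regimen),
                "pfs": _curve_to_dict(s.pfs, curve_dir, f"{config.name}_{s.name}_pfs"),
                "os": _curve_to_dict(s.os, curve_dir, f"{config.name}_{s.name}_os"),
                "post_progression_cost_rate": s.post_progression_cost_rate,
            }
            for s in config.strategies
        ],
    }


def scenario_from_dict(data: dict, base_dir: str = ".") -> ScenarioConfig:
    if not isinstance(data, dict):
        raise ScenarioValidationError("<root>", "scenario document must be a mapping")
    for req in ("name", "strategies", "comparator"):
        if req not in data:
            raise ScenarioValidationError(req, "required key missing")
    strategies = []
    for i, sd in enumerate(data["strategies"]):
        key = f"strategies[{i}]"
        for req in ("name", "regimen", "pfs", "os"):
            if req not in sd:
                raise ScenarioValidationError(f"{key}.{req}", "required key missing")
        strategies.append(Strategy(
            name=sd["name"],
            regimen=_regimen_from_dict(sd["regimen"], f"{key}.regimen"),
            pfs=_curve_from_dict(sd["pfs"], base_dir, f"{key}.pfs"),
            os=_curve_from_dict(sd["os"], base_dir, f"{key}.os"),
            post_progression_cost_rate=sd.get("post_progression_cost_rate", 0.0),
        ))
    util = data.get("utilities", {})
    try:
        utilities = UtilitySet(on_treatment=util.get("on_treatment", 0.84),
                               progressive=util.get("progressive", 0.50))
    except ValueError as exc:
        raise ScenarioValidationError("utilities", str(exc)) from exc
    try:
        return ScenarioConfig(
            name=data["name"],
            strategies=strategies,
            comparator=data["comparator"],
            utilities=utilities,
            horizon=float(data.get("horizon", 5.0)),
            discount_rate=float(data.get("discount_rate", 0.0)),
            wtp=float(data.get("wtp", 100000.0)),
            mmr_split=data.get("mmr_split", {"dmmr": 0.33, "pmmr": 0.67}),
            seed=data.get("seed"),
            metadata=data.get("metadata", {}),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ScenarioValidationError):
            raise
        raise ScenarioValidationError("<root>", str(exc)) from exc


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a YAML/JSON scenario file."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    config = scenario_from_dict(data, base_dir=os.path.dirname(os.path.abspath(path)))
    logger.info("loaded scenario %s: %d strategies, horizon %.1f y, WTP $%.0f",
                config.name, len(config.strategies), config.horizon, config.wtp)
    return config


def save_scenario(config: ScenarioConfig, path, curve_dir: Optional[str] = None) -> None:
    """Write the scenario as YAML; step curves go to CSV files in
    ``curve_dir`` (default: alongside the scenario file)."""
    path = os.fspath(path)
    base_dir = os.path.dirname(os.path.abspath(path)) or "."
    if curve_dir is None:
        curve_dir = base_dir
    os.makedirs(curve_dir, exist_ok=True)
    doc = scenario_to_dict(config, curve_dir=curve_dir)
    rel = os.path.relpath(curve_dir, start=base_dir)
    if rel != ".":  # curve paths are stored relative to the scenario file
        for sd in doc["strategies"]:
            for key in ("pfs", "os"):
                if "csv" in sd[key]:
                    sd[key]["csv"] = os.path.join(rel, sd[key]["csv"])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def scenario_hash(config: ScenarioConfig) -> str:
    """Deterministic digest of the full scenario (provenance header)."""
    doc = scenario_to_dict(config, curve_dir=None)
    blob = json.dumps(doc, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# -- pipeline -----------------------------------------------------------

RESULT_COLUMNS = ["total_cost", "incremental_cost", "incremental_effect",
                  "pfly", "qa_pflys", "qalys", "icer", "dominance"]


def run_pipeline(config: ScenarioConfig, output_dir: Optional[str] = None,
                 effect_measure: str = "qa_pflys") -> CEAResult:
    """Run the partitioned survival CEA end to end for one scenario.

    Deterministic given the config; when ``output_dir`` is given, writes the
    incremental table as ``cea_results.csv`` (strategy rows; total cost,
    incremental cost/effect, PFLY, QA-PFLYS, QALY, ICER columns) with a
    provenance header carrying the config hash and seed.
    """
    logger.info("cea: %d strategies vs %s over %.1f years (discount %.1f%%)",
                len(config.strategies), config.comparator, config.horizon,
                100 * config.discount_rate)
    result = run_cea(config.strategies, config.utilities, config.horizon,
                     config.comparator, config.discount_rate, effect_measure)
    for name, o in result.outcomes.items():
        logger.info("  %-12s cost $%.0f  QA-PFLYS %.3f  QALY %.3f",
                    name, o.total_cost, o.qa_pflys, o.qalys)
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        out = os.path.join(output_dir, "cea_results.csv")
        table = result.table[RESULT_COLUMNS]
        with open(out, "w", encoding="utf-8") as fh:
            fh.write(f"# psmcea scenario={config.name} "
                     f"config_sha256={scenario_hash(config)} seed={config.seed}\n")
            table.to_csv(fh, float_format="%.6f")
        logger.info("wrote %s", out)
    return result
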