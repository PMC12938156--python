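"""Deterministic cost-effectiveness engine.

Combines three-state occupancy with utilities and regimen costs into
per-strategy expected cost and effectiveness, then the incremental (ICER)
analysis against a comparator.

Effectiveness is measured primarily in quality-adjusted progression-free
life-years saved (QA-PFLYS): the utility-weighted integral of the
progression-free proportion over the model horizon.  QALYs add the
utility-weighted post-progression time and are reported as a secondary
measure.  The incremental cost-effectiveness ratio is

    ICER = (C_strategy - C_comparator) / (E_strategy - E_comparator)

with dominance flagged (rather than a negative ICER printed) when the sign
pattern calls for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .regimens import Regimen, ToxicityProfile, drug_cost, toxicity_cost
from .survival import (
    DEFAULT_GRID_STEP,
    StateOccupancy,
    SurvivalCurve,
    apply_hazard_ratio,
    grid_integral,
    make_grid,
    partition,
)

__all__ = [
    "UtilitySet",
    "Strategy",
    "StrategyOutcome",
    "CEAResult",
    "qa_pflys",
    "qalys",
    "pf_life_years",
    "total_cost",
    "evaluate_strategy",
    "incremental_analysis",
    "run_cea",
    "net_monetary_benefit",
]


@dataclass
class UtilitySet:
    """Health-state utilities: on-treatment progression-free and progressive."""

    on_treatment: float = 0.84
    progressive: float = 0.50

    def __post_init__(self) -> None:
        for name in ("on_treatment", "progressive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"utility {name} must lie in [0, 1], got {v}")


@dataclass
class Strategy:
    """One treatment arm: regimen plus its PFS and OS curves.

    ``hazard_adjust`` is a proportional-hazards perturbation applied to both
    curves (S ** hazard_adjust); the probabilistic sensitivity analysis uses
    it to propagate uncertainty in treatment effect.  ``post_progression_
    cost_rate`` is a flat USD/year cost while in the post-progression state.
    """

    name: str
    regimen: Regimen
    pfs: SurvivalCurve
    os: SurvivalCurve
    post_progression_cost_rate: float = 0.0
    hazard_adjust: float = 1.0

    def effective_curves(self) -> Tuple[SurvivalCurve, SurvivalCurve]:
        if self.hazard_adjust == 1.0:
            return self.pfs, self.os
        return (apply_hazard_ratio(self.pfs, self.hazard_adjust),
                apply_hazard_ratio(self.os, self.hazard_adjust))


@dataclass
class StrategyOutcome:
    name: str
    total_cost: float
    qa_pflys: float
    qalys: float
    pfly: float


@dataclass
class CEAResult:
    """Per-strategy outcomes plus the incremental table vs the comparator."""

    outcomes: Dict[str, StrategyOutcome]
    comparator: str
    table: pd.DataFrame

    def icer(self, strategy: str) -> float:
        return float(self.table.loc[strategy, "icer"])


def _occ_method(occupancy: StateOccupancy) -> str:
    return "step" if occupancy.stepwise else "simpson"


def _toxicity_reduction(occupancy: StateOccupancy, utilities: UtilitySet,
                        toxicity: Optional[ToxicityProfile], horizon: float,
                        discount_rate: float) -> float:
    """QA-PFLYS lost to the toxicity utility multiplier over its window."""
    if toxicity is None or toxicity.probability == 0.0 or toxicity.duration == 0.0:
        return 0.0
    window = min(toxicity.duration, horizon)
    base = grid_integral(occupancy.times, occupancy.pf, discount_rate, upper=window,
                         method=_occ_method(occupancy))
    return utilities.on_treatment * toxicity.probability * (1.0 - toxicity.utility) * base


def qa_pflys(occupancy: StateOccupancy, utilities: UtilitySet,
             toxicity: Optional[ToxicityProfile], horizon: float,
             discount_rate: float = 0.0) -> float:
    """Quality-adjusted progression-free life-years over the horizon.

    Integrates on-treatment utility x PF(t) x discount factor; during the
    toxicity window the utility is reduced by the probability-weighted
    toxicity multiplier.
    """
    base = grid_integral(occupancy.times, occupancy.pf, discount_rate, upper=horizon,
                         method=_occ_method(occupancy))
    return (utilities.on_treatment * base
            - _toxicity_reduction(occupancy, utilities, toxicity, horizon, discount_rate))


def qalys(occupancy: StateOccupancy, utilities: UtilitySet,
          toxicity: Optional[ToxicityProfile], horizon: float,
          discount_rate: float = 0.0) -> float:
    """QA-PFLYS plus utility-weighted post-progression life-years."""
    pp_term = utilities.progressive * grid_integral(
        occupancy.times, occupancy.pp, discount_rate, upper=horizon,
        method=_occ_method(occupancy))
    return qa_pflys(occupancy, utilities, toxicity, horizon, discount_rate) + pp_term


def pf_life_years(occupancy: StateOccupancy, horizon: float,
                  discount_rate: float = 0.0) -> float:
    """Unadjusted (utility-free) progression-free life-years."""
    return grid_integral(occupancy.times, occupancy.pf, discount_rate, upper=horizon,
                         method=_occ_method(occupancy))


def total_cost(strategy: Strategy, horizon: float, discount_rate: float = 0.0,
               occupancy: Optional[StateOccupancy] = None) -> float:
    """Expected cost: drug + expected toxicity + post-progression care."""
    pfs, os_curve = strategy.effective_curves()
    cost = drug_cost(strategy.regimen, pfs, horizon, discount_rate)
    cost += toxicity_cost(strategy.regimen.toxicity)
    if strategy.post_progression_cost_rate:
        if occupancy is None:
            occupancy = partition(os_curve, pfs, make_grid(horizon, DEFAULT_GRID_STEP,
                                                           pfs, os_curve))
        cost += strategy.post_progression_cost_rate * grid_integral(
            occupancy.times, occupancy.pp, discount_rate, upper=horizon,
            method=_occ_method(occupancy))
    return cost


def evaluate_strategy(strategy: Strategy, utilities: UtilitySet, horizon: float,
                      discount_rate: float = 0.0,
                      grid: Optional[np.ndarray] = None) -> StrategyOutcome:
    """Run one strategy through the partitioned survival model."""
    pfs, os_curve = strategy.effective_curves()
    if grid is None:
        grid = make_grid(horizon, DEFAULT_GRID_STEP, pfs, os_curve)
    occ = partition(os_curve, pfs, grid)
    tox = strategy.regimen.toxicity
    return StrategyOutcome(
        name=strategy.name,
        total_cost=total_cost(strategy, horizon, discount_rate, occupancy=occ),
        qa_pflys=qa_pflys(occ, utilities, tox, horizon, discount_rate),
        qalys=qalys(occ, utilities, tox, horizon, discount_rate),
        pfly=pf_life_years(occ, horizon, discount_rate),
    )


def _normalize(results) -> List[Tuple[str, float, float, dict]]:
    """Accept StrategyOutcomes or (name, cost, effect) tuples."""
    rows = []
    for r in results:
        if isinstance(r, StrategyOutcome):
            rows.append((r.name, r.total_cost, r.qa_pflys,
                         {"qalys": r.qalys, "pfly": r.pfly}))
        else:
            name, cost, effect = r
            rows.append((name, float(cost), float(effect), {}))
    return rows


def incremental_analysis(results: Iterable, comparator: str) -> pd.DataFrame:
    """Pairwise incremental analysis of each strategy against the comparator.

    Returns one row per strategy with total cost, incremental cost and
    effectiveness, the ICER (NaN when undefined or when a dominance flag
    applies), and the dominance label.
    """
    rows = _normalize(results)
    names = [r[0] for r in rows]
    if comparator not in names:
        raise ValueError(f"comparator {comparator!r} not among strategies {names}")
    if len(rows) < 2:
        raise ValueError("incremental analysis needs at least two strategies")
    base = next(r for r in rows if r[0] == comparator)
    out = []
    for name, cost, effect, extra in rows:
        rec = {"strategy": name, "total_cost": cost, "effect": effect, **extra}
        if name == comparator:
            rec.update(incremental_cost=np.nan, incremental_effect=np.nan,
                       icer=np.nan, dominance="")
        else:
            d_cost = cost - base[1]
            d_eff = effect - base[2]
            if d_cost < 0 and d_eff > 0:
                dom = "dominant"
            elif d_cost > 0 and d_eff < 0:
                dom = "dominated"
            else:
                dom = ""
            icer = np.nan
            if d_eff != 0.0 and not dom:
                icer = d_cost / d_eff
            rec.update(incremental_cost=d_cost, incremental_effect=d_eff,
                       icer=icer, dominance=dom)
        out.append(rec)
    return pd.DataFrame(out).set_index("strategy")


def run_cea(strategies: Iterable[Strategy], utilities: UtilitySet, horizon: float,
            comparator: str, discount_rate: float = 0.0,
            effect_measure: str = "qa_pflys") -> CEAResult:
    """Evaluate every strategy and build the incremental table."""
    strategies = list(strategies)
    outcomes = {s.name: evaluate_strategy(s, utilities, horizon, discount_rate)
                for s in strategies}
    if effect_measure not in ("qa_pflys", "qalys"):
        raise ValueError("effect_measure must be 'qa_pflys' or 'qalys'")
    triples = [(o.name, o.total_cost, getattr(o, effect_measure))
               for o in outcomes.values()]
    table = incremental_analysis(triples, comparator)
    table["qa_pflys"] = [outcomes[n].qa_pflys for n in table.index]
    table["qalys"] = [outcomes[n].qalys for n in table.index]
    table["pfly"] = [outcomes[n].pfly for n in table.index]
    return CEAResult(outcomes=outcomes, comparator=comparator, table=table)


def net_monetary_benefit(cost: float, effect: float, wtp: float) -> float:
    """NMB = WTP x effect - cost; highest NMB wins at that threshold."""
    return wtp * effect - cost
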