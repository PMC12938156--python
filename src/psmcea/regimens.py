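"""Regimen schedules, stopping rules, and expected drug / toxicity costs.

Each strategy is an induction phase (immunotherapy + carboplatin/paclitaxel
every 3 weeks for 6 cycles) optionally followed by a maintenance phase at
its own interval, truncated by a dose cap, a total-treatment-time cap, and
the model horizon.  Costs accrue per administration: the first
``guaranteed_doses`` administrations are always delivered (patients receive
3 cycles before any progression is acted on), later ones are weighted by
the probability of still being progression-free at the dose time.

The per-administration price of the immunotherapy component is carried as
an explicit parameter (``immuno_price``) with a per-phase multiplier
(maintenance doses are larger), so that total drug cost is exactly linear
in that price — the closed-form break-even price in the threshold analysis
rests on this linearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Optional

import numpy as np

from .survival import WEEK, SurvivalCurve, evaluate

#: dosing intervals, in years
CYCLE_Q3W = 3 * WEEK
CYCLE_Q4W = 4 * WEEK
CYCLE_Q6W = 6 * WEEK
#: induction length: 6 cycles every 3 weeks
INDUCTION_WEEKS = 18.0

__all__ = [
    "DosePhase",
    "ToxicityProfile",
    "Regimen",
    "Dose",
    "dose_times",
    "expected_doses",
    "drug_cost",
    "priced_administrations",
    "toxicity_cost",
    "reprice",
    "REGIMEN_PRESETS",
    "CYCLE_Q3W",
    "CYCLE_Q4W",
    "CYCLE_Q6W",
]


@dataclass
class DosePhase:
    """One dosing phase: fixed interval, optional dose cap, cost per dose.

    ``price_multiplier`` is the number of immunotherapy price units charged
    per administration in this phase (e.g. 2 when the maintenance dose is
    double the induction dose).
    """

    interval: float
    max_doses: Optional[int]
    cost_per_dose: float
    stop_on_progression: bool = True
    price_multiplier: float = 0.0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("dose interval must be positive")
        if self.cost_per_dose < 0:
            raise ValueError("cost per dose must be non-negative")
        if self.max_doses is not None and self.max_doses < 0:
            raise ValueError("max_doses must be non-negative or None (unbounded)")


@dataclass
class ToxicityProfile:
    """Grade >=3 toxicity: one-time expected cost plus a utility multiplier
    applied (probability-weighted) over ``duration`` years from model start."""

    probability: float
    cost: float
    utility: float = 1.0
    duration: float = INDUCTION_WEEKS * WEEK

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("toxicity probability must lie in [0, 1]")
        if not 0.0 <= self.utility <= 1.0:
            raise ValueError("toxicity utility multiplier must lie in [0, 1]")
        if self.cost < 0 or self.duration < 0:
            raise ValueError("toxicity cost and duration must be non-negative")

    @property
    def expected_utility_multiplier(self) -> float:
        """Probability-weighted utility multiplier during the toxicity window."""
        return 1.0 - self.probability * (1.0 - self.utility)


@dataclass
class Regimen:
    """A full treatment strategy: induction, optional maintenance, caps."""

    name: str
    induction: DosePhase
    toxicity: ToxicityProfile
    maintenance: Optional[DosePhase] = None
    guaranteed_doses: int = 3
    #: all doses stop at this many years from treatment start (None = no cap)
    max_treatment_years: Optional[float] = None
    #: current per-administration price of the immunotherapy component
    immuno_price: float = 0.0

    def __post_init__(self) -> None:
        if self.induction.max_doses is None:
            raise ValueError("induction phase must have a finite dose cap")
        if self.guaranteed_doses < 0 or self.guaranteed_doses > self.induction.max_doses:
            raise ValueError("guaranteed_doses must lie within the induction schedule")
        if self.immuno_price < 0:
            raise ValueError("immuno_price must be non-negative")

    @property
    def induction_end(self) -> float:
        """Time at which the induction phase completes."""
        return self.induction.max_doses * self.induction.interval


class Dose(NamedTuple):
    time: float
    cost: float
    phase: str
    price_multiplier: float
    stop_on_progression: bool


def dose_times(regimen: Regimen, horizon: float) -> List[Dose]:
    """Deterministic dose schedule, truncated by caps and the horizon.

    Induction doses fall at 0, i, 2i, ...; maintenance doses start at the
    end of the induction phase and continue at the maintenance interval.
    A dose is scheduled only strictly before every applicable cap.
    """
    cap = horizon
    if regimen.max_treatment_years is not None:
        cap = min(cap, regimen.max_treatment_years)
    out: List[Dose] = []
    ind = regimen.induction
    for k in range(ind.max_doses):
        t = k * ind.interval
        if t >= cap:
            break
        out.append(Dose(t, ind.cost_per_dose, "induction",
                        ind.price_multiplier, ind.stop_on_progression))
    m = regimen.maintenance
    if m is not None and (m.max_doses is None or m.max_doses > 0):
        start = regimen.induction_end
        k = 0
        while m.max_doses is None or k < m.max_doses:
            t = start + k * m.interval
            if t >= cap:
                break
            out.append(Dose(t, m.cost_per_dose, "maintenance",
                            m.price_multiplier, m.stop_on_progression))
            k += 1
    return out


def _dose_weights(regimen: Regimen, pfs: SurvivalCurve, horizon: float):
    """Schedule plus the probability each dose is actually delivered."""
    doses = dose_times(regimen, horizon)
    weights = np.ones(len(doses))
    for j, d in enumerate(doses):
        if j >= regimen.guaranteed_doses and d.stop_on_progression:
            weights[j] = evaluate(pfs, d.time)
    return doses, weights


def expected_doses(regimen: Regimen, pfs: SurvivalCurve, horizon: float) -> Dict[str, float]:
    """Expected number of administrations per phase under the PFS curve."""
    doses, weights = _dose_weights(regimen, pfs, horizon)
    out = {"induction": 0.0, "maintenance": 0.0}
    for d, w in zip(doses, weights):
        out[d.phase] += w
    return out


def drug_cost(regimen: Regimen, pfs: SurvivalCurve, horizon: float,
              discount_rate: float = 0.0) -> float:
    """Expected discounted drug cost: sum over scheduled doses of
    cost x delivery probability x discount factor."""
    doses, weights = _dose_weights(regimen, pfs, horizon)
    if not doses:
        return 0.0
    t = np.array([d.time for d in doses])
    c = np.array([d.cost for d in doses])
    return float(np.sum(c * weights * np.exp(-discount_rate * t)))


def priced_administrations(regimen: Regimen, pfs: SurvivalCurve, horizon: float,
                           discount_rate: float = 0.0) -> float:
    """Expected discounted number of immunotherapy price units delivered.

    Drug cost is linear in the immunotherapy price p with slope equal to
    this quantity: C(p) = C(p0) + N * (p - p0).
    """
    doses, weights = _dose_weights(regimen, pfs, horizon)
    if not doses:
        return 0.0
    t = np.array([d.time for d in doses])
    mult = np.array([d.price_multiplier for d in doses])
    return float(np.sum(mult * weights * np.exp(-discount_rate * t)))


def toxicity_cost(profile: ToxicityProfile) -> float:
    """Expected one-time toxicity cost: probability x cost, at model start."""
    return profile.probability * profile.cost


def reprice(regimen: Regimen, new_price: float) -> Regimen:
    """Return a copy of the regimen with the immunotherapy component priced
    at ``new_price`` per induction administration (maintenance scales by its
    phase multiplier)."""
    if new_price < 0:
        raise ValueError("price must be non-negative")
    delta = new_price - regimen.immuno_price

    def shift(phase: Optional[DosePhase]) -> Optional[DosePhase]:
        if phase is None:
            return None
        return replace(phase, cost_per_dose=phase.cost_per_dose + phase.price_multiplier * delta)

    return replace(regimen, induction=shift(regimen.induction),
                   maintenance=shift(regimen.maintenance), immuno_price=new_price)


# -- bundled regimens --------------------------------------------------
#
# 2024 USD per-cycle costs.  Triplet induction costs are for the
# immunotherapy + carboplatin + paclitaxel combination every 3 weeks for 6
# cycles; chemotherapy alone is $1,126/cycle.  Maintenance administrations
# use a double immunotherapy dose every 6 weeks (dostarlimab, pembrolizumab)
# or a 1500 mg dose every 4 weeks (durvalumab, 1120 mg during induction).

CHEMO_COST_PER_CYCLE = 1126.0
TOX_COST_IO = 9784.0
TOX_COST_CHEMO = 9163.0
TOX_UTILITY = 0.70


def tc() -> Regimen:
    return Regimen(
        name="TC",
        induction=DosePhase(CYCLE_Q3W, 6, CHEMO_COST_PER_CYCLE),
        toxicity=ToxicityProfile(0.53, TOX_COST_CHEMO, TOX_UTILITY),
    )


def pembrolizumab_tc() -> Regimen:
    # 200 mg q3w x6 with chemo, then 400 mg q6w to a 2-year total cap
    price = 13464.0 - CHEMO_COST_PER_CYCLE
    return Regimen(
        name="PEM-TC",
        induction=DosePhase(CYCLE_Q3W, 6, 13464.0, price_multiplier=1.0),
        maintenance=DosePhase(CYCLE_Q6W, None, 24676.0, price_multiplier=2.0),
        max_treatment_years=2.0,
        toxicity=ToxicityProfile(0.63, TOX_COST_IO, TOX_UTILITY),
        immuno_price=price,
    )


def dostarlimab_tc(maintenance_years: float = 3.0) -> Regimen:
    # 500 mg q3w x6 with chemo, then 1000 mg q6w, up to 42 maintenance
    # cycles, capped at 3 years of treatment (2-year variant for comparison)
    price = 14462.0 - CHEMO_COST_PER_CYCLE
    suffix = f"-{maintenance_years:g}y"
    return Regimen(
        name=f"DOS-TC{suffix}",
        induction=DosePhase(CYCLE_Q3W, 6, 14462.0, price_multiplier=1.0),
        maintenance=DosePhase(CYCLE_Q6W, 42, 26672.0, price_multiplier=2.0),
        max_treatment_years=maintenance_years,
        toxicity=ToxicityProfile(0.71, TOX_COST_IO, TOX_UTILITY),
        immuno_price=price,
    )


def durvalumab_tc(maintenance_years: Optional[float] = None) -> Regimen:
    # 1120 mg q3w x6 with chemo, then 1500 mg q4w until progression
    # (optionally capped at 2 or 3 years to compare with the other drugs)
    price = 10146.0 - CHEMO_COST_PER_CYCLE
    name = "DUO-TC" if maintenance_years is None else f"DUO-TC-{maintenance_years:g}y"
    return Regimen(
        name=name,
        induction=DosePhase(CYCLE_Q3W, 6, 10146.0, price_multiplier=1.0),
        maintenance=DosePhase(CYCLE_Q4W, None, 12081.0,
                              price_multiplier=12081.0 / price),
        max_treatment_years=maintenance_years,
        toxicity=ToxicityProfile(0.54, TOX_COST_IO, TOX_UTILITY),
        immuno_price=price,
    )


REGIMEN_PRESETS = {
    "TC": tc,
    "PEM-TC": pembrolizumab_tc,
    "DOS-TC-2y": lambda: dostarlimab_tc(2.0),
    "DOS-TC-3y": lambda: dostarlimab_tc(3.0),
    "DUO-TC": durvalumab_tc,
    "DUO-TC-2y": lambda: durvalumab_tc(2.0),
    "DUO-TC-3y": lambda: durvalumab_tc(3.0),
}
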