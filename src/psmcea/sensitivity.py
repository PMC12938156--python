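"""Threshold (break-even price), one-way/tornado, and probabilistic
sensitivity analysis over the deterministic engine.

The threshold analysis exploits the exact linearity of total drug cost in
the per-administration immunotherapy price p:

    C(p) = C(p0) + N * (p - p0),   N = expected discounted priced doses

so the price at which the ICER equals the willingness-to-pay threshold has
the closed form  p* = p0 - (dC(p0) - WTP * dE) / N.

One-way analysis re-runs the engine with a single parameter at its low and
high bound; the tornado sorts the resulting ICER ranges by width.  The
probabilistic analysis draws every parameter independently per iteration
(gamma for costs, beta for probabilities and utilities, lognormal for the
hazard-scale treatment-effect perturbation) and summarizes the fraction of
iterations in which each strategy has the highest net monetary benefit as
a cost-effectiveness acceptability curve over a WTP grid.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .config import ScenarioConfig
from .engine import Strategy, incremental_analysis, run_cea
from .regimens import priced_administrations, reprice

__all__ = [
    "ParameterSpec",
    "ThresholdResult",
    "OneWayResult",
    "PSAResult",
    "set_parameter",
    "break_even_price",
    "break_even_price_bisect",
    "one_way",
    "tornado",
    "run_psa",
    "default_owsa_parameters",
    "default_psa_parameters",
    "scenario_icer",
    "DEFAULT_WTP_GRID",
]

DEFAULT_WTP_GRID = np.arange(0.0, 300001.0, 10000.0)


@dataclass
class ParameterSpec:
    """One scenario parameter: dotted path, base value, OWSA bounds, and a
    PSA distribution.

    Paths address the scenario tree, e.g. ``utilities.on_treatment`` or
    ``strategies.PEM-TC.regimen.toxicity.probability``.  The special leaf
    ``immuno_price`` reprices every phase of the regimen consistently.
    Distributions: ``gamma`` (costs), ``beta`` (probabilities/utilities,
    truncated to [0, 1]), ``lognormal`` (positive ratios), ``normal``, or
    ``fixed``.  ``se`` defaults to 20% of base for gamma and 10% for the
    bounded families.
    """

    name: str
    base: float
    low: Optional[float] = None
    high: Optional[float] = None
    distribution: str = "fixed"
    se: Optional[float] = None

    _FAMILIES = ("gamma", "beta", "lognormal", "normal", "fixed")

    def __post_init__(self) -> None:
        if self.distribution not in self._FAMILIES:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.low is None:
            self.low = self.base
        if self.high is None:
            self.high = self.base
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"{self.name}: bounds must bracket the base value "
                f"({self.low} <= {self.base} <= {self.high} fails)")
        if self.distribution == "beta" and not (0.0 <= self.base <= 1.0):
            raise ValueError(f"{self.name}: beta requires a [0,1]-valued base")
        if self.se is None:
            self.se = (0.2 if self.distribution == "gamma" else 0.1) * abs(self.base)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n independent values from the PSA distribution."""
        if self.distribution == "fixed" or self.se == 0.0:
            return np.full(n, self.base)
        m, s = self.base, self.se
        if self.distribution == "gamma":
            shape = (m / s) ** 2
            return rng.gamma(shape, m / shape, size=n)
        if self.distribution == "beta":
            nu = m * (1.0 - m) / s**2 - 1.0
            if nu <= 0:  # SE infeasible for a beta; fall back to clipped normal
                return np.clip(rng.normal(m, s, size=n), 0.0, 1.0)
            a, b = m * nu, (1.0 - m) * nu
            return rng.beta(a, b, size=n)
        if self.distribution == "lognormal":
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            return rng.lognormal(mu, np.sqrt(sigma2), size=n)
        return rng.normal(m, s, size=n)


# -- parameter plumbing -------------------------------------------------

def _resolve(scenario: ScenarioConfig, name: str):
    """Walk the dotted path; return (parent object, final attribute)."""
    parts = name.split(".")
    obj = scenario
    i = 0
    while i < len(parts) - 1:
        seg = parts[i]
        if seg == "strategies":
            i += 1
            obj = scenario.strategy(parts[i])
        else:
            obj = getattr(obj, seg)
        i += 1
    return obj, parts[-1]


def _apply(scenario: ScenarioConfig, name: str, value: float) -> None:
    """Set one parameter in place (scenario must be a private copy)."""
    try:
        parent, attr = _resolve(scenario, name)
    except (AttributeError, KeyError) as exc:
        raise KeyError(f"unknown parameter {name!r}") from exc
    if attr == "immuno_price":
        # parent is the Regimen; repricing shifts every phase consistently
        holder = next(s for s in scenario.strategies if s.regimen is parent)
        holder.regimen = reprice(parent, value)
        return
    if not hasattr(parent, attr):
        raise KeyError(f"unknown parameter {name!r}")
    setattr(parent, attr, value)


def set_parameter(scenario: ScenarioConfig, name: str, value: float) -> ScenarioConfig:
    """Return a deep copy of the scenario with one parameter overridden."""
    out = copy.deepcopy(scenario)
    _apply(out, name, value)
    return out


def _evaluate(scenario: ScenarioConfig):
    return run_cea(scenario.strategies, scenario.utilities, scenario.horizon,
                   scenario.comparator, scenario.discount_rate)


def scenario_icer(scenario: ScenarioConfig, strategy: str):
    """ICER (and the incremental pieces) of one strategy vs the comparator."""
    res = _evaluate(scenario)
    row = res.table.loc[strategy]
    return float(row["icer"]), float(row["incremental_cost"]), float(row["incremental_effect"])


# -- threshold (break-even price) ---------------------------------------

@dataclass
class ThresholdResult:
    strategy: str
    wtp: float
    current_price: float
    break_even_price: Optional[float]
    #: required decrease per administration (None when no finite break-even)
    decrease: Optional[float]
    base_icer: float


def break_even_price(scenario: ScenarioConfig, strategy: str,
                     wtp: Optional[float] = None) -> ThresholdResult:
    """Per-administration immunotherapy price at which the strategy's ICER
    vs the comparator equals the willingness-to-pay threshold (closed form)."""
    wtp = scenario.wtp if wtp is None else wtp
    strat = scenario.strategy(strategy)
    icer, d_cost, d_eff = scenario_icer(scenario, strategy)
    if d_eff <= 0:
        return ThresholdResult(strategy, wtp, strat.regimen.immuno_price,
                               None, None, icer)
    pfs, _ = strat.effective_curves()
    n_priced = priced_administrations(strat.regimen, pfs, scenario.horizon,
                                      scenario.discount_rate)
    if n_priced <= 0:
        raise ValueError(f"strategy {strategy!r} has no priced administrations")
    p0 = strat.regimen.immuno_price
    p_star = p0 - (d_cost - wtp * d_eff) / n_priced
    return ThresholdResult(strategy, wtp, p0, p_star, p0 - p_star, icer)


def break_even_price_bisect(scenario: ScenarioConfig, strategy: str,
                            wtp: Optional[float] = None,
                            bracket: tuple = (0.0, 1e6)) -> float:
    """Break-even price by root-finding on the full engine (verification
    route for the closed form; slower but assumption-free)."""
    wtp = scenario.wtp if wtp is None else wtp
    path = f"strategies.{strategy}.regimen.immuno_price"

    def gap(price: float) -> float:
        sc = set_parameter(scenario, path, price)
        _, d_cost, d_eff = scenario_icer(sc, strategy)
        return d_cost - wtp * d_eff

    return float(optimize.brentq(gap, *bracket, xtol=1e-6))


# -- one-way / tornado --------------------------------------------------

@dataclass
class OneWayResult:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float
    icer_base: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def one_way(scenario: ScenarioConfig, strategy: str,
            parameter: ParameterSpec) -> OneWayResult:
    """ICER with the parameter at its low and high bound, all else at base."""
    base_icer, _, _ = scenario_icer(scenario, strategy)
    icer_lo, _, _ = scenario_icer(set_parameter(scenario, parameter.name, parameter.low),
                                  strategy)
    icer_hi, _, _ = scenario_icer(set_parameter(scenario, parameter.name, parameter.high),
                                  strategy)
    return OneWayResult(parameter.name, parameter.low, parameter.high,
                        icer_lo, icer_hi, base_icer)


def tornado(scenario: ScenarioConfig, strategy: str,
            parameters: Sequence[ParameterSpec]) -> pd.DataFrame:
    """One-way results for every parameter, sorted by ICER range width."""
    rows = [one_way(scenario, strategy, p) for p in parameters]
    df = pd.DataFrame([{
        "parameter": r.parameter, "low": r.low, "high": r.high,
        "icer_low": r.icer_low, "icer_high": r.icer_high,
        "icer_base": r.icer_base, "width": r.width,
    } for r in rows])
    return df.sort_values("width", ascending=False, kind="mergesort").reset_index(drop=True)


def _bounded(base: float, frac: float, cap: Optional[float] = None):
    lo, hi = base * (1 - frac), base * (1 + frac)
    if cap is not None:
        hi = min(hi, cap)
    return lo, hi


def default_owsa_parameters(scenario: ScenarioConfig, strategy: str) -> List[ParameterSpec]:
    """Default one-way ranges: costs and durations +/-20%; probabilities and
    utilities +/-10% truncated to [0, 1] (a 20% band on a 0.84 utility would
    exceed the feasible range; 10% mirrors the PSA's SE convention)."""
    strat = scenario.strategy(strategy)
    reg = strat.regimen
    comp = scenario.strategy(scenario.comparator)
    prefix = f"strategies.{strategy}.regimen"
    specs: List[ParameterSpec] = []
    if reg.immuno_price > 0:
        lo, hi = _bounded(reg.immuno_price, 0.2)
        specs.append(ParameterSpec(f"{prefix}.immuno_price", reg.immuno_price, lo, hi,
                                   distribution="gamma"))
    if reg.max_treatment_years is not None:
        lo, hi = _bounded(reg.max_treatment_years, 0.2)
        specs.append(ParameterSpec(f"{prefix}.max_treatment_years",
                                   reg.max_treatment_years, lo, hi))
    lo, hi = _bounded(reg.toxicity.cost, 0.2)
    specs.append(ParameterSpec(f"{prefix}.toxicity.cost", reg.toxicity.cost, lo, hi,
                               distribution="gamma"))
    lo, hi = _bounded(reg.toxicity.probability, 0.1, cap=1.0)
    specs.append(ParameterSpec(f"{prefix}.toxicity.probability",
                               reg.toxicity.probability, lo, hi, distribution="beta"))
    lo, hi = _bounded(comp.regimen.toxicity.cost, 0.2)
    specs.append(ParameterSpec(f"strategies.{comp.name}.regimen.toxicity.cost",
                               comp.regimen.toxicity.cost, lo, hi, distribution="gamma"))
    for uname, uval in (("on_treatment", scenario.utilities.on_treatment),
                        ("progressive", scenario.utilities.progressive)):
        lo, hi = _bounded(uval, 0.1, cap=1.0)
        specs.append(ParameterSpec(f"utilities.{uname}", uval, lo, hi,
                                   distribution="beta"))
    return specs


# -- probabilistic sensitivity analysis ---------------------------------

def default_psa_parameters(scenario: ScenarioConfig) -> List[ParameterSpec]:
    """Default PSA distributions: gamma on every cost (SE 20% of base), beta
    on probabilities and utilities (SE 10%), lognormal on the per-strategy
    treatment-effect perturbation (SE 10% around 1)."""
    specs: List[ParameterSpec] = []
    for s in scenario.strategies:
        prefix = f"strategies.{s.name}.regimen"
        if s.regimen.immuno_price > 0:
            specs.append(ParameterSpec(f"{prefix}.immuno_price",
                                       s.regimen.immuno_price, distribution="gamma"))
        else:
            specs.append(ParameterSpec(f"{prefix}.induction.cost_per_dose",
                                       s.regimen.induction.cost_per_dose,
                                       distribution="gamma"))
        specs.append(ParameterSpec(f"{prefix}.toxicity.cost",
                                   s.regimen.toxicity.cost, distribution="gamma"))
        specs.append(ParameterSpec(f"{prefix}.toxicity.probability",
                                   s.regimen.toxicity.probability, distribution="beta"))
        if s.name != scenario.comparator:
            specs.append(ParameterSpec(f"strategies.{s.name}.hazard_adjust",
                                       1.0, distribution="lognormal"))
    specs.append(ParameterSpec("utilities.on_treatment",
                               scenario.utilities.on_treatment, distribution="beta"))
    specs.append(ParameterSpec("utilities.progressive",
                               scenario.utilities.progressive, distribution="beta"))
    return specs


@dataclass
class PSAResult:
    """Per-iteration (cost, effect) pairs and the CEAC over a WTP grid."""

    n_sims: int
    seed: int
    strategies: List[str]
    costs: np.ndarray    # (n_sims, n_strategies)
    effects: np.ndarray  # (n_sims, n_strategies)
    wtp_grid: np.ndarray
    ceac: pd.DataFrame   # index: wtp, columns: strategies, values: P(optimal)

    def iterations_frame(self) -> pd.DataFrame:
        recs = []
        for j, name in enumerate(self.strategies):
            for i in range(self.n_sims):
                recs.append({"iteration": i, "strategy": name,
                             "cost": self.costs[i, j], "effect": self.effects[i, j]})
        return pd.DataFrame(recs)


def _ceac_from_draws(costs: np.ndarray, effects: np.ndarray,
                     wtp_grid: np.ndarray) -> np.ndarray:
    """Fraction of iterations each strategy has the highest NMB; ties go to
    the lowest-cost strategy (deterministic)."""
    n, k = costs.shape
    out = np.zeros((len(wtp_grid), k))
    for w, wtp in enumerate(wtp_grid):
        nmb = wtp * effects - costs
        best = nmb.max(axis=1, keepdims=True)
        tied = nmb >= best  # exact ties possible with fixed parameters
        winner = np.where(tied, costs, np.inf).argmin(axis=1)
        out[w] = np.bincount(winner, minlength=k) / n
    return out


def run_psa(scenario: ScenarioConfig, n_sims: int, seed: int,
            wtp_grid: Optional[np.ndarray] = None,
            parameters: Optional[Sequence[ParameterSpec]] = None) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    Every parameter is drawn independently per iteration (no correlation
    structure), the deterministic engine is re-run, and the CEAC records the
    probability each strategy is optimal at each willingness-to-pay value.
    Reproducible: the same seed yields bit-identical results.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if parameters is None:
        parameters = default_psa_parameters(scenario)
    rng = np.random.default_rng(seed)
    draws = {p.name: p.sample(rng, n_sims) for p in parameters}
    names = [s.name for s in scenario.strategies]
    costs = np.empty((n_sims, len(names)))
    effects = np.empty((n_sims, len(names)))
    for i in range(n_sims):
        sc = copy.deepcopy(scenario)
        for pname, vals in draws.items():
            _apply(sc, pname, float(vals[i]))
        res = _evaluate(sc)
        for j, name in enumerate(names):
            o = res.outcomes[name]
            costs[i, j] = o.total_cost
            effects[i, j] = o.qa_pflys
    ceac = _ceac_from_draws(costs, effects, wtp_grid)
    ceac_df = pd.DataFrame(ceac, index=pd.Index(wtp_grid, name="wtp"), columns=names)
    return PSAResult(n_sims=n_sims, seed=seed, strategies=names, costs=costs,
                     effects=effects, wtp_grid=wtp_grid, ceac=ceac_df)
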