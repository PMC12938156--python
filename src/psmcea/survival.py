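"""Survival curves and three-state partitioning.

A partitioned survival model derives health-state occupancy directly from
two survival functions: overall survival OS(t) and progression-free
survival PFS(t).  At every time point the cohort splits into

    progression-free  PF(t) = PFS(t)
    post-progression  PP(t) = OS(t) - PFS(t)
    dead               D(t) = 1 - OS(t)

This module houses the curve container (digitized Kaplan-Meier steps or
parametric exponential/Weibull forms), proportional-hazards transforms,
the partition itself, and discounted restricted-area integrals that the
cost-effectiveness engine accumulates life-years with.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import integrate

DAYS_PER_YEAR = 365.25
WEEK = 7.0 / DAYS_PER_YEAR
#: default evaluation grid step (one week, in years)
DEFAULT_GRID_STEP = WEEK
#: digitized PFS may exceed OS by up to this much (pixel noise) before erroring
CROSSING_CLAMP_TOL = 5e-3

__all__ = [
    "SurvivalCurve",
    "StateOccupancy",
    "HazardRatio",
    "CurveCrossingError",
    "evaluate",
    "apply_hazard_ratio",
    "partition",
    "restricted_area",
    "make_grid",
    "grid_integral",
    "read_curve_csv",
    "write_curve_csv",
    "DAYS_PER_YEAR",
    "WEEK",
]


class CurveCrossingError(ValueError):
    """PFS exceeds OS beyond the clamping tolerance."""


@dataclass
class HazardRatio:
    """A proportional-hazards effect size with optional confidence bounds."""

    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"hazard ratio must be positive, got {self.value}")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.value <= self.ci_high):
                raise ValueError(
                    f"hazard ratio {self.value} outside CI [{self.ci_low}, {self.ci_high}]"
                )

    @property
    def ci_half_width(self) -> Optional[float]:
        if self.ci_low is None or self.ci_high is None:
            return None
        return (self.ci_high - self.ci_low) / 2.0


@dataclass
class SurvivalCurve:
    """A non-increasing survival function S(t), t in years.

    ``kind`` selects the representation:

    - ``"step"``: right-continuous step function through ``(times, probs)``
      pairs, the natural form of a digitized Kaplan-Meier curve.  Past the
      last observed time the ``extrapolation`` policy applies: ``"hold"``
      keeps the last value; ``"exp_tail"`` continues with an exponential
      fitted to the final quarter of the follow-up window.
    - ``"exponential"``: S(t) = exp(-rate * t).
    - ``"weibull"``: S(t) = exp(-(rate * t) ** shape); shape 1 recovers the
      exponential.
    """

    kind: str
    times: Optional[np.ndarray] = None
    probs: Optional[np.ndarray] = None
    rate: Optional[float] = None
    shape: float = 1.0
    label: str = ""
    extrapolation: str = "hold"

    def __post_init__(self) -> None:
        if self.kind not in ("step", "exponential", "weibull"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.kind == "step":
            if self.times is None or self.probs is None:
                raise ValueError("step curve requires times and probs")
            self.times = np.asarray(self.times, dtype=float)
            self.probs = np.asarray(self.probs, dtype=float)
            if self.times.ndim != 1 or self.times.shape != self.probs.shape:
                raise ValueError("times and probs must be matching 1-D arrays")
            if self.times[0] != 0.0:
                raise ValueError("step curve must start at t=0")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")
            if self.probs[0] != 1.0:
                raise ValueError("survival at t=0 must be 1")
            if np.any(np.diff(self.probs) > 1e-12):
                raise ValueError("survival probabilities must be non-increasing")
            if np.any(self.probs < 0) or np.any(self.probs > 1):
                raise ValueError("survival probabilities must lie in [0, 1]")
            if self.extrapolation not in ("hold", "exp_tail"):
                raise ValueError(f"unknown extrapolation {self.extrapolation!r}")
        else:
            if self.rate is None or self.rate <= 0:
                raise ValueError("parametric curve requires rate > 0")
            if self.shape <= 0:
                raise ValueError("Weibull shape must be positive")

    # -- constructors -------------------------------------------------

    @classmethod
    def step(cls, times: Iterable[float], probs: Iterable[float], label: str = "",
             extrapolation: str = "hold") -> "SurvivalCurve":
        return cls(kind="step", times=np.asarray(list(times), dtype=float),
                   probs=np.asarray(list(probs), dtype=float), label=label,
                   extrapolation=extrapolation)

    @classmethod
    def exponential(cls, rate: Optional[float] = None, median: Optional[float] = None,
                    label: str = "") -> "SurvivalCurve":
        if (rate is None) == (median is None):
            raise ValueError("give exactly one of rate or median")
        if rate is None:
            rate = np.log(2.0) / median
        return cls(kind="exponential", rate=float(rate), label=label)

    @classmethod
    def weibull(cls, rate: float, shape: float, label: str = "") -> "SurvivalCurve":
        return cls(kind="weibull", rate=float(rate), shape=float(shape), label=label)

    # -- evaluation ---------------------------------------------------

    def _tail_rate(self) -> float:
        """Exponential rate fitted to the last quarter of a step curve."""
        t_max = self.times[-1]
        mask = (self.times >= 0.75 * t_max) & (self.probs > 0)
        t, p = self.times[mask], self.probs[mask]
        if len(t) < 2:
            return 0.0
        # least-squares slope of log S against t
        slope = np.polyfit(t, np.log(p), 1)[0]
        return max(-slope, 0.0)

    def __call__(self, t):
        return evaluate(self, t)

    @property
    def median(self) -> float:
        """Time at which S(t) first reaches 0.5."""
        if self.kind == "exponential":
            return np.log(2.0) / self.rate
        if self.kind == "weibull":
            return np.log(2.0) ** (1.0 / self.shape) / self.rate
        below = np.nonzero(self.probs <= 0.5)[0]
        if len(below) == 0:
            return np.inf
        return float(self.times[below[0]])


def evaluate(curve: SurvivalCurve, t) -> np.ndarray | float:
    """Evaluate S(t).  Step curves are right-continuous; parametric curves
    use the closed form.  Negative times are a domain error."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival curves are defined for t >= 0")
    if curve.kind == "exponential":
        out = np.exp(-curve.rate * t_arr)
    elif curve.kind == "weibull":
        out = np.exp(-((curve.rate * t_arr) ** curve.shape))
    else:
        idx = np.searchsorted(curve.times, t_arr, side="right") - 1
        idx = np.clip(idx, 0, len(curve.times) - 1)
        out = curve.probs[idx]
        beyond = t_arr > curve.times[-1]
        if np.any(beyond) and curve.extrapolation == "exp_tail":
            lam = curve._tail_rate()
            tail = curve.probs[-1] * np.exp(-lam * (t_arr - curve.times[-1]))
            out = np.where(beyond, tail, out)
    return out if np.ndim(t) else float(out)


def apply_hazard_ratio(curve: SurvivalCurve, hr) -> SurvivalCurve:
    """Proportional-hazards transform: S_new(t) = S(t) ** hr.

    For step curves the powers are applied to the stored probabilities; for
    exponential curves the rate scales by hr; for Weibull curves the rate
    scales by hr ** (1/shape), which is the same pointwise power.
    """
    value = hr.value if isinstance(hr, HazardRatio) else float(hr)
    if value <= 0:
        raise ValueError("hazard ratio must be positive")
    label = f"{curve.label} x HR {value:g}" if curve.label else f"HR {value:g}"
    if curve.kind == "step":
        return SurvivalCurve.step(curve.times, curve.probs ** value, label=label,
                                  extrapolation=curve.extrapolation)
    if curve.kind == "exponential":
        return SurvivalCurve.exponential(rate=curve.rate * value, label=label)
    return SurvivalCurve.weibull(rate=curve.rate * value ** (1.0 / curve.shape),
                                 shape=curve.shape, label=label)


@dataclass
class StateOccupancy:
    """Proportions progression-free / post-progression / dead on a time grid.

    ``stepwise`` records that both source curves were step functions, so the
    proportions are themselves right-continuous steps and integrate exactly
    by rectangle sums whenever the grid contains the jump times.
    """

    times: np.ndarray
    pf: np.ndarray
    pp: np.ndarray
    dead: np.ndarray
    stepwise: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pf = np.asarray(self.pf, dtype=float)
        self.pp = np.asarray(self.pp, dtype=float)
        self.dead = np.asarray(self.dead, dtype=float)
        total = self.pf + self.pp + self.dead
        if np.max(np.abs(total - 1.0)) > 1e-9:
            raise ValueError("state proportions must sum to 1 at every grid point")
        for name, arr in (("pf", self.pf), ("pp", self.pp), ("dead", self.dead)):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"{name} proportions must lie in [0, 1]")
        if np.any(np.diff(self.dead) < -1e-9):
            raise ValueError("dead proportion must be non-decreasing")
        if np.any(np.diff(self.pf) > 1e-9):
            raise ValueError("progression-free proportion must be non-increasing")


def make_grid(horizon: float, step: float = DEFAULT_GRID_STEP,
              *curves: SurvivalCurve) -> np.ndarray:
    """Uniform grid on [0, horizon] at the given step, endpoint included.

    Any step curves passed contribute their jump times to the grid, which
    makes rectangle integration of the resulting occupancy exact.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    grid = np.arange(0.0, horizon, step)
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    knots = [c.times[c.times < horizon] for c in curves if c is not None and c.kind == "step"]
    if knots:
        grid = np.union1d(grid, np.concatenate(knots))
    return grid


def partition(os_curve: SurvivalCurve, pfs_curve: SurvivalCurve,
              grid: np.ndarray, clamp_tol: float = CROSSING_CLAMP_TOL) -> StateOccupancy:
    """Split the cohort into PF / PP / dead along the grid.

    Digitized PFS may sit a hair above OS from pixel error; excesses up to
    ``clamp_tol`` are clamped down to OS with a warning, larger ones raise
    :class:`CurveCrossingError` naming the first offending time.
    """
    grid = np.asarray(grid, dtype=float)
    os_vals = np.asarray(evaluate(os_curve, grid), dtype=float)
    pf_vals = np.asarray(evaluate(pfs_curve, grid), dtype=float)
    excess = pf_vals - os_vals
    worst = np.max(excess) if len(excess) else 0.0
    if worst > clamp_tol:
        t_bad = grid[np.argmax(excess > clamp_tol)]
        raise CurveCrossingError(
            f"PFS exceeds OS by {worst:.4g} (tolerance {clamp_tol:g}), "
            f"first at t={t_bad:.4g} years"
        )
    if worst > 1e-12:
        warnings.warn(
            f"PFS exceeded OS by up to {worst:.4g}; clamped to OS (digitization noise)",
            stacklevel=2,
        )
        pf_vals = np.minimum(pf_vals, os_vals)
    return StateOccupancy(times=grid, pf=pf_vals, pp=os_vals - pf_vals,
                          dead=1.0 - os_vals,
                          stepwise=(os_curve.kind == "step" and pfs_curve.kind == "step"))


def _discount_segment(t0, t1, rate: float):
    """Integral of exp(-rate*t) over [t0, t1], vectorized; the expm1 form
    stays accurate as rate -> 0."""
    if rate == 0.0:
        return np.asarray(t1) - np.asarray(t0)
    return np.exp(-rate * np.asarray(t0)) * (-np.expm1(-rate * (np.asarray(t1) - t0)) / rate)


def restricted_area(curve: SurvivalCurve, horizon: float,
                    discount_rate: float = 0.0) -> float:
    """Discounted restricted area under the curve over [0, horizon]:
    integral of S(t) * exp(-discount_rate * t) dt.

    Step curves integrate exactly segment by segment (including the hold or
    exponential-tail extrapolation past the last observed time); parametric
    curves use adaptive quadrature.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if discount_rate < 0:
        raise ValueError("discount rate must be non-negative")
    r = discount_rate
    if curve.kind != "step":
        val, _ = integrate.quad(
            lambda t: evaluate(curve, t) * np.exp(-r * t),
            0.0, horizon, epsabs=1e-12, epsrel=1e-12, limit=500,
        )
        return val
    knots = curve.times[curve.times < horizon]
    vals = curve.probs[: len(knots)]
    edges = np.append(knots, min(curve.times[-1], horizon))
    total = 0.0
    for v, t0, t1 in zip(vals, edges[:-1], edges[1:]):
        total += v * _discount_segment(t0, t1, r)
    t_last = curve.times[-1]
    if horizon > t_last:  # extrapolated tail
        s_last = curve.probs[-1]
        if curve.extrapolation == "exp_tail":
            lam = curve._tail_rate()
        else:
            lam = 0.0
        # integral of s_last * exp(-lam*(t-t_last)) * exp(-r t) over [t_last, horizon]
        total += s_last * np.exp(lam * t_last) * _discount_segment(t_last, horizon, lam + r)
    return total


def grid_integral(times: np.ndarray, values: np.ndarray, discount_rate: float = 0.0,
                  upper: Optional[float] = None, method: str = "simpson") -> float:
    """Integral of values(t) * exp(-discount_rate * t) on the grid, optionally
    truncated at ``upper``.

    ``method="simpson"`` suits smooth (parametric) occupancies; ``"step"``
    treats the values as a right-continuous step function and sums exact
    discounted rectangles, which is error-free when the grid contains every
    jump time.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if upper is not None:
        if upper <= times[0]:
            return 0.0
        if upper < times[-1]:
            if method == "step":
                idx = np.searchsorted(times, upper, side="right") - 1
                v_up = values[idx]
            else:
                v_up = float(np.interp(upper, times, values))
            keep = times < upper
            times = np.append(times[keep], upper)
            values = np.append(values[keep], v_up)
    if method == "step":
        seg = _discount_segment(times[:-1], times[1:], discount_rate)
        return float(np.sum(values[:-1] * seg))
    if method != "simpson":
        raise ValueError(f"unknown integration method {method!r}")
    integrand = values * np.exp(-discount_rate * times)
    return float(integrate.simpson(integrand, x=times))


# -- digitized-curve CSV dialect --------------------------------------

CURVE_CSV_HEADER = "time_years,survival"


def write_curve_csv(curve: SurvivalCurve, path) -> None:
    """Write a step curve as ``time_years,survival`` with 6 decimal places."""
    if curve.kind != "step":
        raise ValueError("only step curves are written to the digitized-curve CSV")
    lines = [CURVE_CSV_HEADER]
    lines += [f"{t:.6f},{p:.6f}" for t, p in zip(curve.times, curve.probs)]
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_curve_csv(path, label: str = "", extrapolation: str = "hold") -> SurvivalCurve:
    """Read the ``time_years,survival`` digitized-curve CSV."""
    if hasattr(path, "read"):
        fh = path
        close = False
    else:
        fh = open(path, "r", encoding="utf-8")
        close = True
    try:
        header = fh.readline().strip()
        if header.replace(" ", "") != CURVE_CSV_HEADER:
            raise ValueError(f"expected header '{CURVE_CSV_HEADER}', got {header!r}")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    finally:
        if close:
            fh.close()
    times = data[:, 0]
    # digitized values can carry rounding jitter; snap tiny violations and
    # collapse times that collide at the file's decimal resolution (keeping
    # the last, i.e. lowest, survival value)
    probs = np.minimum.accumulate(np.clip(data[:, 1], 0.0, 1.0))
    keep = np.append(np.diff(times) > 0, True)
    return SurvivalCurve.step(times[keep], probs[keep], label=label,
                              extrapolation=extrapolation)
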