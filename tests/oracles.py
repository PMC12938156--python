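"""Independent oracles used by the test suite.

These deliberately avoid the package's integration and accumulation code
paths: event times are drawn by inverse transform directly from a survival
curve, and per-patient costs and quality-adjusted progression-free time are
accumulated with closed-form per-patient discount integrals.
"""

from __future__ import annotations

import numpy as np

from psmcea.regimens import Regimen, dose_times
from psmcea.survival import SurvivalCurve


def sample_event_times(curve: SurvivalCurve, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-transform sample of event times T with P(T > t) = S(t).

    For a step curve with hold extrapolation, mass S(t_last) never fails
    within the observed window; those draws return +inf.
    """
    u = rng.uniform(size=n)
    if curve.kind == "exponential":
        return -np.log(u) / curve.rate
    if curve.kind == "weibull":
        return (-np.log(u)) ** (1.0 / curve.shape) / curve.rate
    # smallest k with S(t_k) < u; -probs is ascending
    idx = np.searchsorted(-curve.probs, -u, side="right")
    out = np.full(n, np.inf)
    inside = idx < len(curve.times)
    out[inside] = curve.times[idx[inside]]
    return out


def _disc_int(a, b, rate: float):
    """Integral of exp(-rate*t) over [a, b], vectorized."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if rate == 0.0:
        return b - a
    return (np.exp(-rate * a) - np.exp(-rate * b)) / rate


def mc_patient_level(regimen: Regimen, pfs: SurvivalCurve, utilities, horizon: float,
                     discount_rate: float, n: int, seed: int) -> dict:
    """Patient-level simulation of one regimen against its PFS curve.

    Draws progression times, delivers each scheduled dose if the patient is
    still progression-free at the dose time (the first ``guaranteed_doses``
    always), and accumulates per-patient discounted drug cost and
    quality-adjusted progression-free time with the toxicity utility window.
    Returns means and standard errors.
    """
    rng = np.random.default_rng(seed)
    t_prog = sample_event_times(pfs, n, rng)
    doses = dose_times(regimen, horizon)

    cost = np.zeros(n)
    for j, d in enumerate(doses):
        disc = np.exp(-discount_rate * d.time)
        if j < regimen.guaranteed_doses or not d.stop_on_progression:
            cost += d.cost * disc
        else:
            cost += d.cost * disc * (t_prog > d.time)
    tox = regimen.toxicity
    cost += tox.probability * tox.cost  # expected one-time toxicity cost

    u_on = utilities.on_treatment
    window = min(tox.duration, horizon)
    mult = 1.0 - tox.probability * (1.0 - tox.utility)
    tau = np.minimum(t_prog, horizon)
    early = np.minimum(tau, window)
    qapfly = u_on * mult * _disc_int(0.0, early, discount_rate)
    qapfly += u_on * _disc_int(early, np.maximum(tau, early), discount_rate)

    dose_count = np.zeros(n)
    for j, d in enumerate(doses):
        if j < regimen.guaranteed_doses or not d.stop_on_progression:
            dose_count += 1.0
        else:
            dose_count += (t_prog > d.time)

    def mean_se(x):
        return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(n))

    mc, sc = mean_se(cost)
    mq, sq = mean_se(qapfly)
    md, sd = mean_se(dose_count)
    return {"cost": mc, "cost_se": sc, "qa_pflys": mq, "qa_pflys_se": sq,
            "doses": md, "doses_se": sd}
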