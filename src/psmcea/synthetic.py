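"""Trial-like synthetic PFS/OS curves and complete bundled scenarios.

The generator emulates the inputs a partitioned survival analysis consumes:
Kaplan-Meier step curves for each arm of a randomized trial.  Per patient,
a progression time is drawn from a Weibull (shape 1 = exponential by
default) calibrated to the control-arm median; death follows progression by
an exponential post-progression survival draw, which guarantees OS >= PFS
for every patient and hence at every point of both curves.  The treated arm
applies the trial's hazard ratio through a proportional-hazards rescaling.
Censoring is administrative only, at the end of follow-up.

Bundled scenario presets carry the cost/toxicity/utility parameter set for
the four regimens (dostarlimab, pembrolizumab, durvalumab, each added to
carboplatin + paclitaxel, and chemotherapy alone) together with synthetic
curves standing in for the digitized trial Kaplan-Meier estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from . import regimens as _regimens
from .config import ScenarioConfig
from .engine import Strategy, UtilitySet
from .survival import HazardRatio, SurvivalCurve

__all__ = [
    "TrialSimSpec",
    "simulate_patients",
    "simulate_trial_curves",
    "km_curve",
    "build_scenario",
    "PRESET_SEEDS",
]

#: floor on the post-progression survival median (1 month, in years)
MIN_PP_MEDIAN = 1.0 / 12.0

#: default seeds for the bundled scenario presets (fixed so the bundled
#: scenarios are reproducible documents, not fresh draws)
PRESET_SEEDS = {"dmmr": 2024, "pmmr": 2025}


def _hr_value(hr) -> float:
    return hr.value if isinstance(hr, HazardRatio) else float(hr)


@dataclass
class TrialSimSpec:
    """Conditions for one simulated two-arm trial (sizes are per arm)."""

    n_patients: int
    control_median_pfs: float
    control_median_os: float
    hr_pfs: object  # HazardRatio or float
    hr_os: object = 1.0
    weibull_shape: float = 1.0
    max_follow_up: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients per arm")
        if self.control_median_pfs <= 0 or self.control_median_os <= 0:
            raise ValueError("medians must be positive")
        if self.control_median_os < self.control_median_pfs:
            raise ValueError("control OS median must be >= PFS median")
        if self.max_follow_up <= 0:
            raise ValueError("max_follow_up must be positive")
        if self.weibull_shape <= 0:
            raise ValueError("Weibull shape must be positive")
        for hr in (self.hr_pfs, self.hr_os):
            if _hr_value(hr) <= 0:
                raise ValueError("hazard ratios must be positive")


def _draw_arm(rng: np.random.Generator, n: int, pfs_scale: float, shape: float,
              pp_rate: float) -> pd.DataFrame:
    """Per-patient progression and death times; death = progression + PP draw."""
    prog = pfs_scale * (-np.log(rng.uniform(size=n))) ** (1.0 / shape)
    pp = rng.exponential(1.0 / pp_rate, size=n)
    return pd.DataFrame({"progression_time": prog, "death_time": prog + pp})


def simulate_patients(spec: TrialSimSpec) -> pd.DataFrame:
    """Uncensored per-patient event times for both arms (column ``arm`` in
    {control, treated}); the basis for curve construction and for oracle
    checks such as Cox hazard-ratio recovery."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.weibull_shape
    scale_c = spec.control_median_pfs / np.log(2.0) ** (1.0 / shape)
    pp_median = max(spec.control_median_os - spec.control_median_pfs, MIN_PP_MEDIAN)
    pp_rate_c = np.log(2.0) / pp_median
    hr_p, hr_o = _hr_value(spec.hr_pfs), _hr_value(spec.hr_os)
    scale_t = scale_c * hr_p ** (-1.0 / shape)
    pp_rate_t = pp_rate_c * hr_o
    control = _draw_arm(rng, spec.n_patients, scale_c, shape, pp_rate_c)
    treated = _draw_arm(rng, spec.n_patients, scale_t, shape, pp_rate_t)
    control["arm"] = "control"
    treated["arm"] = "treated"
    return pd.concat([control, treated], ignore_index=True)


def km_curve(event_times: np.ndarray, max_follow_up: float, label: str = "") -> SurvivalCurve:
    """Kaplan-Meier step curve with administrative censoring at follow-up end."""
    event_times = np.asarray(event_times, dtype=float)
    observed = event_times <= max_follow_up
    durations = np.minimum(event_times, max_follow_up)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    probs = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.insert(times, 0, 0.0)
        probs = np.insert(probs, 0, 1.0)
    probs = np.minimum.accumulate(np.clip(probs, 0.0, 1.0))
    probs[0] = 1.0
    return SurvivalCurve.step(times, probs, label=label)


def simulate_trial_curves(spec: TrialSimSpec) -> Dict[str, Tuple[SurvivalCurve, SurvivalCurve]]:
    """Kaplan-Meier (PFS, OS) step curves per arm, reproducible under seed."""
    patients = simulate_patients(spec)
    out = {}
    for arm in ("control", "treated"):
        sub = patients[patients["arm"] == arm]
        pfs = km_curve(sub["progression_time"].to_numpy(), spec.max_follow_up,
                       label=f"{arm} PFS")
        os_curve = km_curve(sub["death_time"].to_numpy(), spec.max_follow_up,
                            label=f"{arm} OS")
        out[arm] = (pfs, os_curve)
    return out


# -- bundled scenarios ---------------------------------------------------
#
# Effect sizes are the published PFS hazard ratios: dMMR — dostarlimab 0.29
# (95% CI 0.16-0.50), pembrolizumab 0.30 (0.19-0.48), durvalumab 0.42
# (0.22-0.80); pMMR — pembrolizumab 0.54 (0.41-0.71), dostarlimab 0.76.
# Control medians are typical of the chemotherapy arms of those trials.
# Post-progression survival is assumed unaffected by prior treatment
# (hr_os = 1): OS gains flow entirely from delayed progression.

DMMR_HRS = {
    "DOS": HazardRatio(0.29, 0.16, 0.50),
    "PEM": HazardRatio(0.30, 0.19, 0.48),
    "DUO": HazardRatio(0.42, 0.22, 0.80),
}
PMMR_HRS = {
    "PEM": HazardRatio(0.54, 0.41, 0.71),
    "DOS": HazardRatio(0.76, 0.57, 1.01),
}
#: simulated cohort size per arm for the bundled presets: large, because the
#: curves stand in for digitized population-level KM estimates that the
#: downstream analysis treats as fixed inputs
PRESET_N_PER_ARM = 5000
DMMR_CONTROL_MEDIANS = (0.64, 2.3)   # PFS, OS in years (~7.7 mo PFS)
PMMR_CONTROL_MEDIANS = (0.725, 2.3)  # ~8.7 mo PFS


def _preset_curves(control_medians, hrs, seed):
    """One shared control arm plus one treated arm per drug (the model
    compares every regimen against a single chemotherapy strategy)."""
    med_pfs, med_os = control_medians
    curves = {}
    base = TrialSimSpec(PRESET_N_PER_ARM, med_pfs, med_os, hr_pfs=1.0,
                        max_follow_up=5.0, seed=seed)
    curves["TC"] = simulate_trial_curves(base)["control"]
    for k, (drug, hr) in enumerate(sorted(hrs.items())):
        spec = TrialSimSpec(PRESET_N_PER_ARM, med_pfs, med_os, hr_pfs=hr,
                            max_follow_up=5.0, seed=seed + 1 + k)
        curves[drug] = simulate_trial_curves(spec)["treated"]
    return curves


def _toy_scenario() -> ScenarioConfig:
    """Exponential curves with closed-form life-year integrals, for analytic
    verification of the full pipeline."""
    tc_pfs = SurvivalCurve.exponential(median=0.75, label="toy TC PFS")
    tc_os = SurvivalCurve.exponential(median=2.0, label="toy TC OS")
    io_pfs = SurvivalCurve.exponential(rate=tc_pfs.rate * 0.5, label="toy IO PFS")
    io_os = SurvivalCurve.exponential(rate=tc_os.rate * 0.5, label="toy IO OS")
    strategies = [
        Strategy("TC", _regimens.tc(), tc_pfs, tc_os),
        Strategy("PEM-TC", _regimens.pembrolizumab_tc(), io_pfs, io_os),
    ]
    return ScenarioConfig(name="toy", strategies=strategies, comparator="TC",
                          metadata={"description": "exponential toy scenario"})


def build_scenario(preset: str, seed: Optional[int] = None) -> ScenarioConfig:
    """Bundled scenario presets: ``dmmr``, ``pmmr``, or ``toy``.

    ``dmmr`` carries six strategies (TC, PEM-TC, DOS-TC 2y/3y, DUO-TC
    2y/3y), ``pmmr`` four (TC, PEM-TC, DOS-TC 2y/3y); both use synthetic
    trial curves.  ``toy`` is a two-strategy exponential scenario for
    analytic tests.
    """
    if preset == "toy":
        return _toy_scenario()
    if preset not in ("dmmr", "pmmr"):
        raise ValueError(f"unknown preset {preset!r}; choose dmmr, pmmr, or toy")
    if seed is None:
        seed = PRESET_SEEDS[preset]
    if preset == "dmmr":
        curves = _preset_curves(DMMR_CONTROL_MEDIANS, DMMR_HRS, seed)
        regimen_map = [
            ("TC", "TC", "TC"),
            ("PEM-TC", "PEM-TC", "PEM"),
            ("DOS-TC-2y", "DOS-TC-2y", "DOS"),
            ("DOS-TC-3y", "DOS-TC-3y", "DOS"),
            ("DUO-TC-2y", "DUO-TC-2y", "DUO"),
            ("DUO-TC-3y", "DUO-TC-3y", "DUO"),
        ]
        hrs = DMMR_HRS
    else:
        curves = _preset_curves(PMMR_CONTROL_MEDIANS, PMMR_HRS, seed)
        regimen_map = [
            ("TC", "TC", "TC"),
            ("PEM-TC", "PEM-TC", "PEM"),
            ("DOS-TC-2y", "DOS-TC-2y", "DOS"),
            ("DOS-TC-3y", "DOS-TC-3y", "DOS"),
        ]
        hrs = PMMR_HRS
    strategies = []
    for strat_name, preset_name, curve_key in regimen_map:
        pfs, os_curve = curves[curve_key]
        strategies.append(Strategy(strat_name, _regimens.REGIMEN_PRESETS[preset_name](),
                                   pfs, os_curve))
    metadata = {
        "subgroup": preset,
        "hazard_ratios": {d: _hr_value(h) for d, h in hrs.items()},
        "n_per_arm": PRESET_N_PER_ARM,
    }
    return ScenarioConfig(name=preset, strategies=strategies, comparator="TC",
                          seed=seed, metadata=metadata)
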