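import copy

import numpy as np
import pytest

from psmcea.config import ScenarioConfig
from psmcea.engine import Strategy, UtilitySet
from psmcea.regimens import DosePhase, Regimen, ToxicityProfile, tc
from psmcea.sensitivity import (
    DEFAULT_WTP_GRID,
    ParameterSpec,
    break_even_price,
    break_even_price_bisect,
    default_owsa_parameters,
    default_psa_parameters,
    one_way,
    run_psa,
    scenario_icer,
    set_parameter,
    tornado,
)
from psmcea.survival import SurvivalCurve


def tiny_scenario(treated_median=1.5, control_median=0.75, immuno_price=5000.0):
    """Small parametric scenario: chemo comparator vs a priced regimen."""
    treated = Regimen(
        name="IO",
        induction=DosePhase(21 / 365.25, 6, 1126.0 + immuno_price, price_multiplier=1.0),
        maintenance=DosePhase(42 / 365.25, None, 2 * immuno_price, price_multiplier=2.0),
        max_treatment_years=2.0,
        toxicity=ToxicityProfile(0.6, 9784.0, 0.70),
        immuno_price=immuno_price,
    )
    strategies = [
        Strategy("TC", tc(), SurvivalCurve.exponential(median=control_median),
                 SurvivalCurve.exponential(median=2.0)),
        Strategy("IO", treated, SurvivalCurve.exponential(median=treated_median),
                 SurvivalCurve.exponential(median=3.0)),
    ]
    return ScenarioConfig(name="tiny", strategies=strategies, comparator="TC")


class TestSetParameter:
    def test_override_does_not_mutate_original(self):
        sc = tiny_scenario()
        out = set_parameter(sc, "utilities.on_treatment", 0.5)
        assert out.utilities.on_treatment == 0.5
        assert sc.utilities.on_treatment == 0.84

    def test_immuno_price_repricing_shifts_both_phases(self):
        sc = tiny_scenario(immuno_price=5000.0)
        out = set_parameter(sc, "strategies.IO.regimen.immuno_price", 6000.0)
        reg = out.strategy("IO").regimen
        assert reg.immuno_price == 6000.0
        assert reg.induction.cost_per_dose == pytest.approx(1126.0 + 6000.0)
        assert reg.maintenance.cost_per_dose == pytest.approx(2 * 6000.0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            set_parameter(tiny_scenario(), "strategies.IO.regimen.nonsense", 1.0)


class TestBreakEvenPrice:
    def test_fixed_point_at_current_icer(self):
        sc = tiny_scenario()
        base_icer, _, _ = scenario_icer(sc, "IO")
        res = break_even_price(sc, "IO", wtp=base_icer)
        assert res.break_even_price == pytest.approx(sc.strategy("IO").regimen.immuno_price,
                                                     abs=1e-6)

    def test_closed_form_matches_bisection(self):
        sc = tiny_scenario()
        res = break_even_price(sc, "IO", wtp=100_000.0)
        root = break_even_price_bisect(sc, "IO", wtp=100_000.0)
        assert res.break_even_price == pytest.approx(root, abs=0.01)

    def test_engine_icer_at_break_even_equals_wtp(self):
        sc = tiny_scenario()
        res = break_even_price(sc, "IO", wtp=100_000.0)
        sc2 = set_parameter(sc, "strategies.IO.regimen.immuno_price", res.break_even_price)
        icer, _, _ = scenario_icer(sc2, "IO")
        assert icer == pytest.approx(100_000.0, rel=1e-6)

    def test_linear_arithmetic_with_known_administration_count(self):
        # 10 guaranteed administrations at price multiplier 1, no discounting:
        # the required decrease is (dC - WTP*dE) / 10 exactly
        reg = Regimen(
            name="flat",
            induction=DosePhase(0.01, 10, 20_000.0, price_multiplier=1.0),
            toxicity=ToxicityProfile(0.0, 0.0),
            guaranteed_doses=10,
            immuno_price=20_000.0,
        )
        strategies = [
            Strategy("TC", tc(), SurvivalCurve.exponential(median=0.75),
                     SurvivalCurve.exponential(median=2.0)),
            Strategy("flat", reg, SurvivalCurve.exponential(median=1.5),
                     SurvivalCurve.exponential(median=3.0)),
        ]
        sc = ScenarioConfig(name="flat", strategies=strategies, comparator="TC")
        _, d_cost, d_eff = scenario_icer(sc, "flat")
        res = break_even_price(sc, "flat", wtp=100_000.0)
        assert res.decrease == pytest.approx((d_cost - 100_000.0 * d_eff) / 10.0, rel=1e-12)

    def test_no_finite_price_when_effect_not_positive(self):
        sc = tiny_scenario(treated_median=0.5)  # worse than control
        res = break_even_price(sc, "IO", wtp=100_000.0)
        assert res.break_even_price is None
        assert res.decrease is None


class TestOneWay:
    def test_degenerate_bounds_return_base_icer(self):
        sc = tiny_scenario()
        base_icer, _, _ = scenario_icer(sc, "IO")
        spec = ParameterSpec("utilities.on_treatment", 0.84)
        res = one_way(sc, "IO", spec)
        assert res.icer_low == res.icer_high == pytest.approx(base_icer, rel=1e-12)

    def test_price_endpoints_follow_exact_linear_relation(self):
        sc = tiny_scenario()
        p0 = sc.strategy("IO").regimen.immuno_price
        _, d_cost, d_eff = scenario_icer(sc, "IO")
        from psmcea.regimens import priced_administrations
        strat = sc.strategy("IO")
        n_priced = priced_administrations(strat.regimen, strat.pfs, sc.horizon)
        spec = ParameterSpec("strategies.IO.regimen.immuno_price", p0,
                             low=0.8 * p0, high=1.2 * p0)
        res = one_way(sc, "IO", spec)
        for p, got in ((spec.low, res.icer_low), (spec.high, res.icer_high)):
            expect = (d_cost + n_priced * (p - p0)) / d_eff
            assert got == pytest.approx(expect, rel=1e-9)

    def test_higher_on_treatment_utility_lowers_icer(self):
        sc = tiny_scenario()
        spec = ParameterSpec("utilities.on_treatment", 0.84, low=0.70, high=0.95)
        res = one_way(sc, "IO", spec)
        assert res.icer_low > res.icer_base > res.icer_high

    def test_inert_parameter_gives_zero_width_bar(self):
        # comparator toxicity utility with zero duration cannot move the ICER
        sc = tiny_scenario()
        sc.strategy("TC").regimen.toxicity = ToxicityProfile(0.5, 9163.0, 0.70,
                                                             duration=0.0)
        spec = ParameterSpec("strategies.TC.regimen.toxicity.utility", 0.70,
                             low=0.4, high=1.0)
        res = one_way(sc, "IO", spec)
        assert res.icer_low == pytest.approx(res.icer_high, rel=1e-12)


class TestTornado:
    def test_single_parameter_single_bar(self):
        sc = tiny_scenario()
        df = tornado(sc, "IO", [ParameterSpec("utilities.on_treatment", 0.84,
                                              low=0.76, high=0.92)])
        assert len(df) == 1

    def test_sorted_by_width_descending(self):
        sc = tiny_scenario()
        df = tornado(sc, "IO", default_owsa_parameters(sc, "IO"))
        widths = df["width"].to_numpy()
        assert np.all(np.diff(widths) <= 1e-9)

    def test_all_fixed_parameters_all_zero_width(self):
        sc = tiny_scenario()
        params = [ParameterSpec("utilities.on_treatment", 0.84),
                  ParameterSpec("utilities.progressive", 0.50)]
        df = tornado(sc, "IO", params)
        assert np.allclose(df["width"], 0.0)


class TestPsa:
    def test_degenerate_distributions_reproduce_deterministic(self):
        sc = tiny_scenario()
        params = [ParameterSpec("utilities.on_treatment", 0.84, distribution="fixed")]
        res = run_psa(sc, n_sims=5, seed=3, parameters=params)
        assert np.all(res.costs == res.costs[0])
        assert set(np.unique(res.ceac.to_numpy())) <= {0.0, 1.0}
        # every iteration equals the base-case engine output
        from psmcea.engine import run_cea
        base = run_cea(sc.strategies, sc.utilities, sc.horizon, sc.comparator)
        for j, name in enumerate(res.strategies):
            assert res.costs[0, j] == pytest.approx(base.outcomes[name].total_cost)
            assert res.effects[0, j] == pytest.approx(base.outcomes[name].qa_pflys)

    def test_ceac_probabilities_sum_to_one(self):
        sc = tiny_scenario()
        res = run_psa(sc, n_sims=60, seed=11)
        sums = res.ceac.sum(axis=1).to_numpy()
        assert np.max(np.abs(sums - 1.0)) < 1e-9
        assert res.ceac.to_numpy().min() >= 0.0
        assert res.ceac.to_numpy().max() <= 1.0

    def test_same_seed_bit_identical(self):
        sc = tiny_scenario()
        a = run_psa(sc, n_sims=40, seed=17)
        b = run_psa(sc, n_sims=40, seed=17)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.effects, b.effects)
        assert a.ceac.equals(b.ceac)

    def test_vanishing_variance_concentrates_on_deterministic(self):
        sc = tiny_scenario()
        base = default_psa_parameters(sc)
        shrunk = [ParameterSpec(p.name, p.base, distribution=p.distribution,
                                se=p.se * 1e-6) for p in base]
        res = run_psa(sc, n_sims=50, seed=5, parameters=shrunk)
        from psmcea.engine import net_monetary_benefit, run_cea
        det = run_cea(sc.strategies, sc.utilities, sc.horizon, sc.comparator)
        for wtp in (50_000.0, 150_000.0, 300_000.0):
            nmbs = {n: net_monetary_benefit(o.total_cost, o.qa_pflys, wtp)
                    for n, o in det.outcomes.items()}
            winner = max(nmbs, key=nmbs.get)
            row = res.ceac.loc[wtp]
            assert row[winner] == pytest.approx(1.0)

    def test_invalid_n_sims(self):
        with pytest.raises(ValueError):
            run_psa(tiny_scenario(), n_sims=0, seed=1)

    def test_wtp_grid_covers_default_thresholds(self):
        assert 100_000.0 in DEFAULT_WTP_GRID
        assert 300_000.0 in DEFAULT_WTP_GRID


class TestParameterSpec:
    def test_bounds_must_bracket_base(self):
        with pytest.raises(ValueError):
            ParameterSpec("x", 1.0, low=2.0, high=3.0)

    def test_beta_requires_unit_interval(self):
        with pytest.raises(ValueError):
            ParameterSpec("x", 2.0, distribution="beta")

    def test_sampling_moments(self, rng):
        spec = ParameterSpec("x", 1000.0, distribution="gamma")
        draws = spec.sample(rng, 40_000)
        assert np.mean(draws) == pytest.approx(1000.0, rel=0.01)
        assert np.std(draws) == pytest.approx(200.0, rel=0.05)
        spec = ParameterSpec("u", 0.84, distribution="beta")
        draws = spec.sample(rng, 40_000)
        assert np.mean(draws) == pytest.approx(0.84, rel=0.01)
        assert draws.min() >= 0.0 and draws.max() <= 1.0
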