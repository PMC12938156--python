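import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psmcea.survival import (
    CurveCrossingError,
    SurvivalCurve,
    apply_hazard_ratio,
    evaluate,
    grid_integral,
    make_grid,
    partition,
    read_curve_csv,
    restricted_area,
    write_curve_csv,
)

LN2 = np.log(2.0)


# -- strategies for random curves ---------------------------------------

@st.composite
def step_curves(draw, max_points: int = 12, t_max: float = 5.0):
    n = draw(st.integers(min_value=1, max_value=max_points))
    gaps = draw(st.lists(st.floats(0.05, 1.0), min_size=n, max_size=n))
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    times = times * (t_max / max(times[-1], t_max))
    drops = draw(st.lists(st.floats(0.0, 0.3), min_size=n, max_size=n))
    probs = np.concatenate([[1.0], 1.0 - np.minimum(np.cumsum(drops), 1.0)])
    return SurvivalCurve.step(times, probs)


class TestEvaluate:
    def test_survival_at_origin_is_one(self):
        for c in (SurvivalCurve.exponential(rate=0.7),
                  SurvivalCurve.weibull(rate=0.5, shape=1.4),
                  SurvivalCurve.step([0, 1, 2], [1, 0.8, 0.6])):
            assert evaluate(c, 0.0) == 1.0

    def test_exponential_median(self):
        c = SurvivalCurve.exponential(rate=LN2 / 1.0)
        assert evaluate(c, 1.0) == pytest.approx(0.5, rel=1e-12)

    def test_step_is_right_continuous(self):
        c = SurvivalCurve.step([0, 1, 2], [1, 0.8, 0.6])
        assert evaluate(c, 1.5) == 0.8
        assert evaluate(c, 1.0) == 0.8  # value jumps at the event time
        assert evaluate(c, 10.0) == 0.6  # hold-last-value beyond follow-up

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            evaluate(SurvivalCurve.exponential(rate=1.0), -0.1)

    def test_exp_tail_extrapolation_decays(self):
        t = np.linspace(0, 3, 13)
        probs = np.exp(-0.5 * t)
        hold = SurvivalCurve.step(t, probs, extrapolation="hold")
        tail = SurvivalCurve.step(t, probs, extrapolation="exp_tail")
        assert evaluate(hold, 5.0) == probs[-1]
        # the fitted tail continues the exponential decay
        assert evaluate(tail, 5.0) == pytest.approx(np.exp(-0.5 * 5.0), rel=1e-6)

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            SurvivalCurve.step([0, 1], [1.0, 1.1])  # increasing
        with pytest.raises(ValueError):
            SurvivalCurve.step([0.5, 1], [1.0, 0.9])  # not starting at 0
        with pytest.raises(ValueError):
            SurvivalCurve.step([0, 1], [0.9, 0.8])  # S(0) != 1
        with pytest.raises(ValueError):
            SurvivalCurve.exponential(rate=-1.0)


class TestHazardRatio:
    def test_identity(self):
        c = SurvivalCurve.step([0, 1, 2], [1, 0.8, 0.6])
        out = apply_hazard_ratio(c, 1.0)
        assert np.allclose(out.probs, c.probs)

    def test_exponential_median_scaling(self):
        # median 12 months, HR 0.30 -> median 40 months
        c = SurvivalCurve.exponential(median=1.0)
        out = apply_hazard_ratio(c, 0.30)
        assert out.median == pytest.approx(1.0 / 0.30, rel=1e-12)
        # pointwise S^hr on a fine grid
        t = np.linspace(0, 5, 501)
        assert np.allclose(evaluate(out, t), evaluate(c, t) ** 0.30, atol=1e-12)

    def test_weibull_pointwise_power(self):
        c = SurvivalCurve.weibull(rate=0.8, shape=1.7)
        out = apply_hazard_ratio(c, 0.42)
        t = np.linspace(0, 5, 101)
        assert np.allclose(evaluate(out, t), evaluate(c, t) ** 0.42, rtol=1e-12)

    def test_step_power(self):
        c = SurvivalCurve.step([0, 1], [1.0, 0.64])
        assert evaluate(apply_hazard_ratio(c, 0.5), 1.0) == pytest.approx(0.8)

    def test_invalid_hr(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(SurvivalCurve.exponential(rate=1.0), 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(step_curves(), st.floats(0.05, 5.0))
    def test_monotone_in_hr(self, curve, hr):
        t = np.linspace(0, 6, 50)
        base = np.asarray(evaluate(curve, t))
        shifted = np.asarray(evaluate(apply_hazard_ratio(curve, hr), t))
        if hr < 1:
            assert np.all(shifted >= base - 1e-12)
        else:
            assert np.all(shifted <= base + 1e-12)


class TestPartition:
    def test_direct_formula(self):
        os_c = SurvivalCurve.step([0, 0.5], [1.0, 0.8])
        pfs_c = SurvivalCurve.step([0, 0.5], [1.0, 0.5])
        occ = partition(os_c, pfs_c, np.array([0.0, 1.0]))
        assert occ.pp[1] == pytest.approx(0.3)
        assert occ.dead[1] == pytest.approx(0.2)

    def test_identical_curves_have_empty_post_progression(self):
        c = SurvivalCurve.exponential(rate=0.4)
        occ = partition(c, c, make_grid(5.0))
        assert np.allclose(occ.pp, 0.0)

    def test_crossing_raises_with_time(self):
        os_c = SurvivalCurve.step([0, 1.0], [1.0, 0.8])
        pfs_c = SurvivalCurve.step([0, 1.0], [1.0, 0.9])
        with pytest.raises(CurveCrossingError, match="t="):
            partition(os_c, pfs_c, np.array([0.0, 1.0, 2.0]))

    def test_small_excess_clamped_with_warning(self):
        os_c = SurvivalCurve.step([0, 1.0], [1.0, 0.800])
        pfs_c = SurvivalCurve.step([0, 1.0], [1.0, 0.803])
        with pytest.warns(UserWarning, match="clamped"):
            occ = partition(os_c, pfs_c, np.array([0.0, 1.5]))
        assert occ.pf[1] == pytest.approx(0.800)
        assert occ.pp[1] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(step_curves(), st.floats(1.0, 4.0))
    def test_conservation(self, os_curve, power):
        # PFS = OS ** power (power >= 1) guarantees PFS <= OS
        pfs = SurvivalCurve.step(os_curve.times, os_curve.probs ** power)
        occ = partition(os_curve, pfs, make_grid(6.0))
        total = occ.pf + occ.pp + occ.dead
        assert np.max(np.abs(total - 1.0)) < 1e-9


class TestRestrictedArea:
    def test_unit_survival(self):
        c = SurvivalCurve.step([0.0], [1.0])
        assert restricted_area(c, 5.0) == pytest.approx(5.0, abs=1e-12)

    def test_exponential_closed_form(self):
        c = SurvivalCurve.exponential(rate=0.2)
        expect = (1 - np.exp(-1.0)) / 0.2
        assert restricted_area(c, 5.0) == pytest.approx(expect, rel=1e-9)

    def test_discounted_closed_form(self):
        lam, r, h = 0.2, 0.03, 5.0
        c = SurvivalCurve.exponential(rate=lam)
        expect = (1 - np.exp(-(lam + r) * h)) / (lam + r)
        assert restricted_area(c, h, discount_rate=r) == pytest.approx(expect, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(step_curves(), st.floats(0.5, 8.0))
    def test_step_area_equals_rectangle_sum(self, curve, horizon):
        # rectangle sum; the hold tail is the last prob times the remaining width
        edges = np.append(curve.times[curve.times < horizon], horizon)
        widths = np.diff(edges)
        expect = float(np.sum(curve.probs[: len(widths)] * widths))
        assert restricted_area(curve, horizon) == pytest.approx(expect, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(step_curves(), st.floats(0.5, 4.0), st.floats(0.0, 0.1))
    def test_monotone_in_horizon_and_discount(self, curve, horizon, rate):
        a = restricted_area(curve, horizon, rate)
        assert restricted_area(curve, horizon + 1.0, rate) >= a - 1e-12
        assert restricted_area(curve, horizon, rate + 0.02) <= a + 1e-12

    def test_grid_integral_step_matches_restricted_area(self):
        c = SurvivalCurve.step([0, 0.7, 1.9, 3.2], [1.0, 0.7, 0.45, 0.2])
        grid = make_grid(5.0, 7.0 / 365.25, c)
        vals = np.asarray(evaluate(c, grid))
        got = grid_integral(grid, vals, 0.03, method="step")
        assert got == pytest.approx(restricted_area(c, 5.0, 0.03), rel=1e-12)


class TestCurveCsv:
    def test_round_trip(self, tmp_path):
        c = SurvivalCurve.step([0, 0.25, 1.5, 3.0], [1.0, 0.81, 0.5, 0.12])
        path = tmp_path / "curve.csv"
        write_curve_csv(c, path)
        back = read_curve_csv(path)
        t = np.linspace(0, 4, 33)
        assert np.allclose(evaluate(back, t), evaluate(c, t), atol=1e-6)
        assert path.read_text().splitlines()[0] == "time_years,survival"

    def test_header_enforced(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("years,surv\n0,1\n")
        with pytest.raises(ValueError, match="header"):
            read_curve_csv(path)
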