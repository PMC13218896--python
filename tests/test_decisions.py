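"""Decision layer: printed worked values, prospect-theory asymmetry,
probability weighting, hyperbolic discounting and delayed choice."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adds.decisions import (
    AgencyContext,
    DiscountParams,
    Gamble,
    ProbWeightParams,
    UtilityParams,
    WORKED_GAMBLE,
    accept_gamble,
    alpha_from_da,
    choose_delayed,
    discount_factor,
    expected_utility,
    indifference_alpha,
    probability_weight,
    utility,
)

CTRL = AgencyContext.control()
HIGH = AgencyContext.high()


class TestUtility:
    @pytest.mark.parametrize("x,ctx,expected", [
        (79.0, CTRL, 50.0),
        (-48.0, CTRL, -50.0),
        (79.0, HIGH, 69.0),
        (-48.0, HIGH, -53.0),
        (0.0, CTRL, 0.0),
        (0.0, HIGH, 0.0),
    ])
    def test_calibrated_anchor_values(self, x, ctx, expected):
        assert utility(x, ctx=ctx) == pytest.approx(expected, abs=1e-9)

    def test_recalibration_solves_arbitrary_anchors(self):
        p = UtilityParams.calibrated((100.0, 40.0), (60.0, 45.0))
        assert utility(100.0, p, CTRL) == pytest.approx(40.0)
        assert utility(-60.0, p, CTRL) == pytest.approx(-45.0)

    @settings(derandomize=True, max_examples=60)
    @given(x=st.floats(0.1, 1e4), a=st.floats(0.36, 1.0))
    def test_gain_shift_dominates_loss_shift(self, x, a):
        ctx = AgencyContext.from_agency(a)
        gain_shift = utility(x, ctx=ctx) - utility(x, ctx=CTRL)
        loss_shift = -(utility(-x, ctx=ctx) - utility(-x, ctx=CTRL))
        assert gain_shift > 0
        assert 0 <= loss_shift < gain_shift

    def test_below_control_agency_keeps_control_curve(self):
        ctx = AgencyContext.from_agency(0.1)
        assert ctx.gain_multiplier == 1.0
        assert ctx.loss_multiplier == 1.0

    def test_invalid_multipliers_rejected(self):
        with pytest.raises(ValueError):
            AgencyContext(agency=0.5, gain_multiplier=0.9)
        with pytest.raises(ValueError):
            AgencyContext(agency=0.5, gain_multiplier=1.1,
                          loss_multiplier=1.3)


class TestGamble:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Gamble.from_pairs((10.0, 0.5), (-5.0, 0.4))

    def test_worked_gamble_expected_utilities(self):
        assert expected_utility(WORKED_GAMBLE, ctx=HIGH) == \
            pytest.approx(8.0, abs=1e-9)
        assert expected_utility(WORKED_GAMBLE, ctx=CTRL) == \
            pytest.approx(0.0, abs=1e-9)

    def test_sure_thing_reduces_to_utility(self):
        g = Gamble.from_pairs((30.0, 1.0))
        assert expected_utility(g, ctx=HIGH) == \
            pytest.approx(utility(30.0, ctx=HIGH))

    def test_risk_reversal_on_the_worked_gamble(self):
        assert accept_gamble(WORKED_GAMBLE, ctx=CTRL) == "indifferent"
        assert accept_gamble(WORKED_GAMBLE, ctx=HIGH) == "accept"

    def test_smaller_win_is_rejected_under_control(self):
        g = Gamble.from_pairs((70.0, 0.5), (-48.0, 0.5))
        assert expected_utility(g, ctx=CTRL) < 0
        assert accept_gamble(g, ctx=CTRL) == "reject"

    def test_identity_weighting_reduces_to_expected_utility(self):
        g = Gamble.from_pairs((20.0, 0.3), (-10.0, 0.7))
        eu = expected_utility(g, ctx=HIGH)
        manual = 0.3 * utility(20.0, ctx=HIGH) + 0.7 * utility(-10.0, ctx=HIGH)
        assert eu == pytest.approx(manual, abs=1e-12)


class TestProbabilityWeighting:
    W = ProbWeightParams(distortion_gamma=0.6,
                         mode="one_parameter_weighting")

    def test_endpoints_are_fixed(self):
        assert probability_weight(0.0, self.W) == 0.0
        assert probability_weight(1.0, self.W) == 1.0

    def test_gamma_one_is_identity(self):
        w = ProbWeightParams(distortion_gamma=1.0,
                             mode="one_parameter_weighting")
        for p in (0.01, 0.3, 0.77, 0.99):
            assert probability_weight(p, w) == pytest.approx(p, abs=1e-12)

    def test_inverse_s_over_and_underweighting(self):
        assert probability_weight(0.01, self.W) > 0.01
        assert probability_weight(0.99, self.W) < 0.99

    def test_strictly_increasing_on_grid(self):
        grid = np.linspace(0.0, 1.0, 101)
        vals = [probability_weight(p, self.W) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_da_modulation_shifts_gamma_with_clipping(self):
        w = ProbWeightParams(0.6, da_modulation=0.2,
                             mode="one_parameter_weighting")
        lo = AgencyContext(agency=0.35, tonic_da=1.0)
        hi = AgencyContext(agency=0.85, gain_multiplier=1.38,
                           loss_multiplier=1.06, tonic_da=50.0)
        assert w.effective_gamma(lo) == pytest.approx(0.6 + 0.2 * (1.0 - 2.25))
        assert w.effective_gamma(hi) == 1.0  # clipped at the identity limit

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            probability_weight(1.2, self.W)


class TestDiscounting:
    def test_no_delay_no_discount(self):
        assert discount_factor(0.0, 1.0) == 1.0

    @pytest.mark.parametrize("t,alpha,expected", [
        (1.0, 1.0, 0.5),
        (30.0, 0.1, 0.25),
    ])
    def test_hyperbolic_closed_form(self, t, alpha, expected):
        assert discount_factor(t, alpha) == pytest.approx(expected)

    def test_strictly_decreasing_to_zero(self):
        ts = np.logspace(-2, 6, 50)
        ds = [discount_factor(t, 0.05) for t in ts]
        assert all(b < a for a, b in zip(ds, ds[1:]))
        assert all(d <= 1.0 for d in ds)
        assert ds[-1] < 1e-3

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1.0, 1.0)

    def test_u_shaped_da_coupling(self):
        p = DiscountParams()
        assert alpha_from_da(p.da_optimum, p) == p.alpha_min
        below = [alpha_from_da(d, p) for d in (0.5, 1.5, 2.5)]
        assert all(b < a for a, b in zip(below, below[1:]))  # falling branch
        above = [alpha_from_da(d, p) for d in (3.5, 4.5, 5.5)]
        assert all(b > a for a, b in zip(above, above[1:]))  # rising branch


class TestDelayedChoice:
    def test_dominant_later_option_wins(self):
        assert choose_delayed((10.0, 0.0), (1000.0, 0.1)) == "later"

    def test_preference_switches_at_analytic_indifference_alpha(self):
        sooner, later = (40.0, 0.0), (80.0, 20.0)
        a_star = indifference_alpha(sooner, later)
        assert a_star > 0
        for eps, expected in ((-1e-4, "later"), (1e-4, "sooner")):
            d = DiscountParams(alpha=a_star * (1 + eps))
            assert choose_delayed(sooner, later, dparams=d) == expected

    def test_exact_tie_defaults_to_sooner(self):
        sooner, later = (40.0, 0.0), (80.0, 20.0)
        d = DiscountParams(alpha=indifference_alpha(sooner, later))
        assert choose_delayed(sooner, later, dparams=d) == "sooner"

    def test_front_end_delay_causes_preference_reversal(self):
        """Sooner-smaller wins at the front; adding a common 20-day delay
        flips the choice to later-larger — impossible under exponential
        discounting."""
        d = DiscountParams(alpha=0.1)
        base = choose_delayed((40.0, 0.0), (70.0, 10.0), dparams=d)
        shifted = choose_delayed((40.0, 20.0), (70.0, 30.0), dparams=d)
        assert base == "sooner"
        assert shifted == "later"

    def test_misordered_delays_rejected(self):
        with pytest.raises(ValueError):
            choose_delayed((10.0, 5.0), (20.0, 1.0))

    def test_raising_agency_below_optimum_favors_later(self):
        """With the tonic-DA proxy below the optimum, higher agency means
        higher DA, lower alpha, and more patient choices on a battery."""
        battery = [((30.0, 0.0), (45.0, t)) for t in (20.0, 40.0, 60.0, 90.0)]
        lo = AgencyContext(agency=0.35, tonic_da=2.0)
        hi = AgencyContext(agency=0.85, gain_multiplier=1.38,
                           loss_multiplier=1.06, tonic_da=2.9)
        d = DiscountParams(curvature=2.0)

        def later_fraction(ctx):
            picks = [choose_delayed(s, l, dparams=d, ctx=ctx)
                     for s, l in battery]
            return picks.count("later") / len(picks)

        assert later_fraction(hi) > later_fraction(lo)


class TestCircuitCoupling:
    def test_context_from_recording_carries_tonic_da(self, small_config):
        from adds.circuit import build_network
        net = build_network(small_config)
        rec = net.run(0.5, seed=1)
        ctx = AgencyContext.from_recording(rec, agency=0.5)
        assert ctx.tonic_da is not None and ctx.tonic_da > 0
        # proxy is bounded by full population at the intrinsic rate
        assert ctx.tonic_da < 1.0 * 10.0
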