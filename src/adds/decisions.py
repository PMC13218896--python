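"""Neuroeconomic decision layer: agency-dependent utility, risky choice,
probability weighting, and hyperbolic temporal discounting.

The core idea: the tonic dopamine state set by the sense of agency scales
the prospect-theory value function asymmetrically — gains are amplified
substantially more than losses.  The default calibration reproduces the
worked utilities of the theory: under control conditions a gain of 79
has utility +50 and a loss of 48 has utility -50 (so a 50/50 gamble
between them is exactly neutral); under high agency the same gain is
worth +69 while the loss only deepens to -53, making the gamble worth +8
and flipping it from indifference to acceptance.

Weighted expected utility is U = sum_i pi(p_i) u(x_i) D(t_i), with pi a
one-parameter inverse-S probability weight (identity by default), u the
two-part power value function, and D(t) = 1/(1 + alpha t) the hyperbolic
discount factor.  The discount rate alpha can be coupled to tonic
dopamine through a U-shaped function with a minimum at an optimum DA
level, capturing the dopamine-overdose logic: moderate increases in DA
reduce discounting, but pushing an already-high DA level further past
the optimum increases it again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .circuit import NetworkConfig, SimulationRecording, classify_da_states

__all__ = [
    "UtilityParams",
    "AgencyContext",
    "Gamble",
    "ProbWeightParams",
    "DiscountParams",
    "utility",
    "probability_weight",
    "expected_utility",
    "accept_gamble",
    "discount_factor",
    "alpha_from_da",
    "choose_delayed",
    "indifference_alpha",
    "WORKED_GAMBLE",
]

EU_TOLERANCE = 1e-9

# tonic-DA proxy of the control circuit state (fraction active x mean
# active rate, a.u.): about half the population at ~4.5 Hz
DA_CONTROL_LEVEL = 2.25


@dataclass(frozen=True)
class UtilityParams:
    """Two-part power value function relative to a reference point.

    u(x) = gain_scale * (x - r)^gain_exponent                 for x >= r
    u(x) = -loss_aversion_lambda * gain_scale * (r - x)^loss_exponent
                                                              for x < r

    The default scale and loss-aversion coefficient are solved from the
    control anchors (gain 79 -> +50, loss 48 -> -50); the 0.88 exponents
    are the canonical prospect-theory curvature.
    """

    gain_exponent: float = 0.88
    loss_exponent: float = 0.88
    gain_scale: float = 50.0 / 79.0 ** 0.88
    loss_aversion_lambda: float = (50.0 / 48.0 ** 0.88) / (50.0 / 79.0 ** 0.88)
    reference_point: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.gain_exponent <= 1 and 0 < self.loss_exponent <= 1):
            raise ValueError("exponents must lie in (0, 1]")
        if self.gain_scale <= 0 or self.loss_aversion_lambda <= 0:
            raise ValueError("gain_scale and loss aversion must be positive")

    @classmethod
    def calibrated(
        cls,
        gain_anchor: tuple[float, float] = (79.0, 50.0),
        loss_anchor: tuple[float, float] = (48.0, 50.0),
        gain_exponent: float = 0.88,
        loss_exponent: float = 0.88,
        reference_point: float = 0.0,
    ) -> "UtilityParams":
        """Solve gain_scale and loss_aversion_lambda from two anchors
        (value magnitude, utility magnitude)."""
        gx, gu = gain_anchor
        lx, lu = loss_anchor
        scale = gu / gx ** gain_exponent
        lam = (lu / lx ** loss_exponent) / scale
        return cls(gain_exponent, loss_exponent, scale, lam, reference_point)


@dataclass(frozen=True)
class AgencyContext:
    """Agency level with its derived dopamine-state multipliers.

    ``gain_multiplier`` and ``loss_multiplier`` scale the utility of gains
    and losses relative to the control calibration; by construction both
    are 1 at control agency and the gain shift always dominates the loss
    shift.  ``tonic_da`` optionally carries the circuit's tonic dopamine
    proxy for discounting/weighting couplings.
    """

    agency: float
    gain_multiplier: float = 1.0
    loss_multiplier: float = 1.0
    tonic_da: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.agency <= 1.0:
            raise ValueError("agency must lie in [0, 1]")
        if self.gain_multiplier < 1.0 or self.loss_multiplier < 1.0:
            raise ValueError("multipliers must be >= 1")
        if self.gain_multiplier - 1.0 < self.loss_multiplier - 1.0 - 1e-12:
            raise ValueError("gain shift must dominate loss shift")

    @classmethod
    def control(cls, a_control: float = 0.35) -> "AgencyContext":
        return cls(agency=a_control, tonic_da=DA_CONTROL_LEVEL)

    @classmethod
    def high(cls, a_high: float = 0.85) -> "AgencyContext":
        return cls.from_agency(a_high)

    @classmethod
    def from_agency(
        cls,
        agency: float,
        a_control: float = 0.35,
        a_high: float = 0.85,
        gain_multiplier_high: float = 69.0 / 50.0,
        loss_multiplier_high: float = 53.0 / 50.0,
        tonic_da: float | None = None,
    ) -> "AgencyContext":
        """Interpolate the multipliers linearly in (multiplier - 1)
        between control (both 1) and the high-agency anchors; agency
        below control keeps both multipliers at 1."""
        frac = max(0.0, (agency - a_control) / (a_high - a_control))
        return cls(
            agency=agency,
            gain_multiplier=1.0 + frac * (gain_multiplier_high - 1.0),
            loss_multiplier=1.0 + frac * (loss_multiplier_high - 1.0),
            tonic_da=tonic_da,
        )

    @classmethod
    def from_recording(
        cls,
        recording: SimulationRecording,
        agency: float,
        **kwargs,
    ) -> "AgencyContext":
        """Derive the tonic-DA proxy (fraction active x mean active rate)
        from a circuit recording."""
        cfg = recording.config
        window = recording.duration - cfg.burn_in
        labels = classify_da_states(recording, window=window,
                                    t_start=cfg.burn_in)
        active = [t for t, lab in zip(recording.da_trains, labels)
                  if lab != "silent"]
        frac = len(active) / len(labels)
        if active:
            rate = float(np.mean([
                1000.0 * np.sum(t.spike_times >= cfg.burn_in) / window
                for t in active
            ]))
        else:
            rate = 0.0
        return cls.from_agency(agency, tonic_da=frac * rate, **kwargs)


@dataclass(frozen=True)
class Gamble:
    """A finite prospect: (value, probability, delay) outcomes.

    Delays default to 0 and are in days.  Probabilities must sum to 1.
    """

    outcomes: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.outcomes) < 1:
            raise ValueError("a gamble needs at least one outcome")
        total = sum(p for _, p, _ in self.outcomes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")
        for _, p, t in self.outcomes:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
            if t < 0:
                raise ValueError("delays must be non-negative")

    @classmethod
    def from_pairs(cls, *pairs: tuple[float, float]) -> "Gamble":
        return cls(tuple((v, p, 0.0) for v, p in pairs))

    @property
    def r(self) -> int:
        return len(self.outcomes)


# the theory's worked 50/50 gamble: win 79 on heads, lose 48 on tails
WORKED_GAMBLE = Gamble.from_pairs((79.0, 0.5), (-48.0, 0.5))


@dataclass(frozen=True)
class ProbWeightParams:
    """One-parameter inverse-S probability weighting (Prelec form).

    identity mode returns p unchanged.  In weighting mode,
    w(p) = exp(-(-ln p)^gamma), which overweights small and underweights
    large probabilities for gamma < 1, with fixed endpoints.
    ``da_modulation`` shifts gamma with the tonic-DA excursion from
    control; the default 0 leaves the distortion independent of dopamine,
    since the direction of that coupling is empirically unresolved.
    """

    distortion_gamma: float = 0.6
    da_modulation: float = 0.0
    mode: Literal["identity", "one_parameter_weighting"] = "identity"

    def __post_init__(self) -> None:
        if not 0.0 < self.distortion_gamma <= 1.0:
            raise ValueError("distortion_gamma must lie in (0, 1]")

    def effective_gamma(self, ctx: "AgencyContext | None") -> float:
        g = self.distortion_gamma
        if (self.da_modulation != 0.0 and ctx is not None
                and ctx.tonic_da is not None):
            g += self.da_modulation * (ctx.tonic_da - DA_CONTROL_LEVEL)
        return min(max(g, 1e-6), 1.0)


@dataclass(frozen=True)
class DiscountParams:
    """Hyperbolic discounting D(t) = 1/(1 + alpha t), alpha in 1/days.

    ``alpha`` is the uncoupled default.  When coupled to tonic dopamine,
    log alpha = log alpha_min + curvature (da - da_optimum)^2: a U shape
    with its minimum (least discounting) at ``da_optimum``.
    """

    alpha: float = 0.01
    da_optimum: float = 3.0
    curvature: float = 0.5
    alpha_min: float = 0.005

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha_min <= 0:
            raise ValueError("alpha and alpha_min must be positive")
        if self.curvature < 0:
            raise ValueError("curvature must be non-negative")


def utility(
    x: float,
    params: UtilityParams | None = None,
    ctx: AgencyContext | None = None,
) -> float:
    """Subjective value of outcome ``x`` in the given agency context."""
    params = params or UtilityParams()
    ctx = ctx or AgencyContext.control()
    d = x - params.reference_point
    if d >= 0:
        return ctx.gain_multiplier * params.gain_scale * d ** params.gain_exponent
    return -(ctx.loss_multiplier * params.loss_aversion_lambda
             * params.gain_scale * (-d) ** params.loss_exponent)


def probability_weight(
    p: float,
    params: ProbWeightParams | None = None,
    ctx: AgencyContext | None = None,
) -> float:
    """Decision weight pi(p); endpoints are exact in both modes."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    params = params or ProbWeightParams()
    if params.mode == "identity":
        return p
    if p in (0.0, 1.0):
        return p
    gamma = params.effective_gamma(ctx)
    return math.exp(-((-math.log(p)) ** gamma))


def discount_factor(t: float, alpha: float) -> float:
    """Hyperbolic discount factor 1/(1 + alpha t)."""
    if t < 0:
        raise ValueError("delay must be non-negative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return 1.0 / (1.0 + alpha * t)


def alpha_from_da(
    tonic_da: float,
    params: DiscountParams | None = None,
) -> float:
    """U-shaped dopamine-to-discount-rate coupling, minimised at the DA
    optimum (the dopamine-overdose logic)."""
    if tonic_da < 0:
        raise ValueError("tonic_da must be non-negative")
    params = params or DiscountParams()
    return params.alpha_min * math.exp(
        params.curvature * (tonic_da - params.da_optimum) ** 2
    )


def _alpha_for(ctx: AgencyContext | None, dparams: DiscountParams) -> float:
    if ctx is not None and ctx.tonic_da is not None:
        return alpha_from_da(ctx.tonic_da, dparams)
    return dparams.alpha


def expected_utility(
    g: Gamble,
    uparams: UtilityParams | None = None,
    wparams: ProbWeightParams | None = None,
    ctx: AgencyContext | None = None,
    dparams: DiscountParams | None = None,
) -> float:
    """Weighted, discounted expected utility sum_i pi(p_i) u(x_i) D(t_i)."""
    uparams = uparams or UtilityParams()
    wparams = wparams or ProbWeightParams()
    ctx = ctx or AgencyContext.control()
    total = 0.0
    for x, p, t in g.outcomes:
        term = probability_weight(p, wparams, ctx) * utility(x, uparams, ctx)
        if t > 0:
            total += term * discount_factor(t, _alpha_for(ctx, dparams or DiscountParams()))
        else:
            total += term
    return total


def accept_gamble(
    g: Gamble,
    uparams: UtilityParams | None = None,
    wparams: ProbWeightParams | None = None,
    ctx: AgencyContext | None = None,
    tolerance: float = EU_TOLERANCE,
) -> str:
    """'accept' when EU > tolerance, 'reject' when EU < -tolerance,
    'indifferent' otherwise."""
    eu = expected_utility(g, uparams, wparams, ctx)
    if eu > tolerance:
        return "accept"
    if eu < -tolerance:
        return "reject"
    return "indifferent"


def choose_delayed(
    sooner: tuple[float, float],
    later: tuple[float, float],
    uparams: UtilityParams | None = None,
    dparams: DiscountParams | None = None,
    ctx: AgencyContext | None = None,
) -> str:
    """Pick between (value, delay) options by discounted utility.

    Exact ties go to the sooner option (the impulsive default).
    """
    (xs, ts), (xl, tl) = sooner, later
    if tl <= ts:
        raise ValueError("later option must have the longer delay")
    uparams = uparams or UtilityParams()
    dparams = dparams or DiscountParams()
    alpha = _alpha_for(ctx, dparams)
    us = utility(xs, uparams, ctx) * discount_factor(ts, alpha)
    ul = utility(xl, uparams, ctx) * discount_factor(tl, alpha)
    return "later" if ul > us else "sooner"


def indifference_alpha(
    sooner: tuple[float, float],
    later: tuple[float, float],
    uparams: UtilityParams | None = None,
    ctx: AgencyContext | None = None,
) -> float:
    """Discount rate at which the two delayed options are exactly tied:
    alpha* = (u_l - u_s) / (u_s t_l - u_l t_s), from equating discounted
    utilities under the hyperbolic form."""
    (xs, ts), (xl, tl) = sooner, later
    uparams = uparams or UtilityParams()
    us = utility(xs, uparams, ctx)
    ul = utility(xl, uparams, ctx)
    denom = us * tl - ul * ts
    if denom == 0:
        raise ValueError("no finite indifference point for this pair")
    return (ul - us) / denom
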