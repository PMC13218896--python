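"""Single-neuron dynamics for the agency-dopamine circuit.

Two point-neuron models are used throughout the package:

* Izhikevich two-variable neurons parameterised for striatal medium spiny
  neurons (MSNs).  MSNs are near-silent at rest (tonic rate 0 Hz) and show
  the characteristic up/down membrane states under fluctuating input.
* Quadratic integrate-and-fire (QIF) neurons for the tonically active
  pallidal and midbrain dopamine populations.  An intrinsic bias current
  turns the QIF neuron into a pacemaker whose rate is set by
  :func:`calibrate_bias_current`.

Units are fixed package-wide: membrane potential in mV, currents in pA,
time in ms.  Integration is explicit Euler with a default step of 0.5 ms;
a spike is recorded at the time of the step in which the membrane crosses
``v_peak``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "IzhikevichParams",
    "QIFParams",
    "NeuronState",
    "SpikeTrain",
    "MSN_DEFAULTS",
    "VP_DEFAULTS",
    "DA_DEFAULTS",
    "step_izhikevich",
    "step_qif",
    "simulate_izhikevich",
    "simulate_qif",
    "qif_period",
    "calibrate_bias_current",
    "IntegrationError",
    "CalibrationError",
]

DT_DEFAULT = 0.5  # ms


class IntegrationError(RuntimeError):
    """Raised when the membrane state diverges (usually dt too large)."""


class CalibrationError(RuntimeError):
    """Raised when no bias current reaches the target rate within bounds."""


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of the two-variable Izhikevich neuron.

    Dynamics::

        C dv/dt = k (v - v_rest)(v - v_threshold) - u + I
          du/dt = a (b (v - v_rest) - u)

    with reset ``v <- c``, ``u <- u + d`` on ``v >= v_peak``.
    """

    capacitance: float = 50.0          # pF
    v_rest: float = -80.0              # mV
    v_threshold: float = -25.0         # mV
    gain_k: float = 1.0
    recovery_rate_a: float = 0.01      # 1/ms
    recovery_coupling_b: float = -20.0  # nS
    reset_c: float = -55.0             # mV
    adaptation_increment_d: float = 150.0  # pA
    v_peak: float = 40.0               # mV

    def __post_init__(self) -> None:
        if not (self.v_rest < self.v_threshold < self.v_peak):
            raise ValueError("require v_rest < v_threshold < v_peak")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if self.recovery_rate_a <= 0:
            raise ValueError("recovery_rate_a must be positive")


@dataclass(frozen=True)
class QIFParams:
    """Parameters of the quadratic integrate-and-fire neuron.

    Dynamics::

        tau dv/dt = (v - v_rest)(v - v_critical) / (v_critical - v_rest)
                    + R (bias_current + I)

    ``v_rest`` is the stable and ``v_critical`` the unstable fixed point of
    the undriven neuron; a suprathreshold ``bias_current`` removes both and
    produces intrinsic pacemaking.  ``noise_sd`` is the standard deviation
    of a per-step white current (pA); pallidal neurons use 0 by default.
    """

    membrane_time_constant: float = 10.0  # ms
    v_rest: float = -65.0                 # mV
    v_critical: float = -50.0             # mV
    reset: float = -65.0                  # mV
    v_peak: float = 30.0                  # mV
    bias_current: float = 0.0             # pA
    noise_sd: float = 0.0                 # pA
    input_resistance: float = 0.1         # mV per pA

    def __post_init__(self) -> None:
        if not (self.v_rest < self.v_critical < self.v_peak):
            raise ValueError("require v_rest < v_critical < v_peak")
        if self.membrane_time_constant <= 0:
            raise ValueError("membrane_time_constant must be positive")
        if self.input_resistance <= 0:
            raise ValueError("input_resistance must be positive")

    @property
    def rheobase(self) -> float:
        """Smallest constant current (pA) that abolishes the fixed points."""
        delta = self.v_critical - self.v_rest
        return delta / (4.0 * self.input_resistance)


# Striatal MSN parameterisation of the Izhikevich model family.
MSN_DEFAULTS = IzhikevichParams()

# Ventral pallidum: fast pacemaker, bias calibrated to 7 Hz at build time.
VP_DEFAULTS = QIFParams(membrane_time_constant=10.0)

# VTA dopamine neurons: slow pacemaker, bias calibrated to ~4.5 Hz.
DA_DEFAULTS = QIFParams(membrane_time_constant=20.0)


@dataclass
class NeuronState:
    """Mutable integration state of one neuron."""

    v: float
    recovery_u: float = 0.0
    time_since_last_spike: float = math.inf


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) of one neuron."""

    neuron_id: int
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.neuron_id < 0:
            raise ValueError("neuron_id must be non-negative")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("spike_times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.spike_times.size)

    def rate(self, duration_ms: float) -> float:
        """Mean firing rate in Hz over ``duration_ms``."""
        return 1000.0 * len(self) / duration_ms

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


def _check_finite(*values: float) -> None:
    for x in values:
        if not math.isfinite(x):
            raise IntegrationError(
                "non-finite membrane state or input; reduce dt"
            )


def step_izhikevich(
    state: NeuronState,
    params: IzhikevichParams,
    input_current: float,
    dt: float = DT_DEFAULT,
) -> tuple[NeuronState, bool]:
    """Advance one Izhikevich neuron by one Euler step.

    Returns the new state and a flag that is True when a spike was emitted
    during this step (membrane reached ``v_peak`` and was reset).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_finite(state.v, state.recovery_u, input_current)
    v, u = state.v, state.recovery_u
    p = params
    if v >= p.v_peak:
        # caller handed us a super-peak state: apply the reset rule
        return (
            NeuronState(p.reset_c, u + p.adaptation_increment_d, 0.0),
            True,
        )
    dv = (p.gain_k * (v - p.v_rest) * (v - p.v_threshold) - u + input_current) / p.capacitance
    du = p.recovery_rate_a * (p.recovery_coupling_b * (v - p.v_rest) - u)
    v_new = v + dt * dv
    u_new = u + dt * du
    _check_finite(v_new, u_new)
    if v_new >= p.v_peak:
        return (
            NeuronState(p.reset_c, u_new + p.adaptation_increment_d, 0.0),
            True,
        )
    return (
        NeuronState(v_new, u_new, state.time_since_last_spike + dt),
        False,
    )


def step_qif(
    state: NeuronState,
    params: QIFParams,
    input_current: float,
    dt: float = DT_DEFAULT,
) -> tuple[NeuronState, bool]:
    """Advance one QIF neuron by one Euler step (noise-free path)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_finite(state.v, input_current)
    p = params
    v = state.v
    if v >= p.v_peak:
        return NeuronState(p.reset, 0.0, 0.0), True
    delta = p.v_critical - p.v_rest
    dv = ((v - p.v_rest) * (v - p.v_critical) / delta
          + p.input_resistance * (p.bias_current + input_current)) / p.membrane_time_constant
    v_new = v + dt * dv
    _check_finite(v_new)
    if v_new >= p.v_peak:
        return NeuronState(p.reset, 0.0, 0.0), True
    return NeuronState(v_new, 0.0, state.time_since_last_spike + dt), False


@njit(cache=True)
def _simulate_izh(v0, u0, C, vr, vt, k, a, b, c, d, vpeak,
                  input_current, dt, n_steps):
    v, u = v0, u0
    count = 0
    times = np.empty(n_steps, dtype=np.float64)
    for i in range(n_steps):
        dv = (k * (v - vr) * (v - vt) - u + input_current) / C
        du = a * (b * (v - vr) - u)
        v = v + dt * dv
        u = u + dt * du
        if v >= vpeak:
            v = c
            u = u + d
            times[count] = (i + 1) * dt
            count += 1
    return times[:count]


@njit(cache=True)
def _simulate_qif(v0, tau, vr, vc, reset, vpeak, R, bias, noise_sd,
                  input_current, dt, n_steps, seed):
    np.random.seed(seed)
    v = v0
    delta = vc - vr
    count = 0
    times = np.empty(n_steps, dtype=np.float64)
    for i in range(n_steps):
        I = bias + input_current
        if noise_sd > 0.0:
            I += noise_sd * np.random.randn()
        dv = ((v - vr) * (v - vc) / delta + R * I) / tau
        v = v + dt * dv
        if v >= vpeak:
            v = reset
            times[count] = (i + 1) * dt
            count += 1
    return times[:count]


def simulate_izhikevich(
    params: IzhikevichParams,
    input_current: float,
    duration_ms: float,
    dt: float = DT_DEFAULT,
    v0: float | None = None,
    u0: float = 0.0,
) -> SpikeTrain:
    """Simulate one Izhikevich neuron under constant current."""
    if dt <= 0 or duration_ms <= 0:
        raise ValueError("dt and duration must be positive")
    p = params
    times = _simulate_izh(
        p.v_rest if v0 is None else v0, u0,
        p.capacitance, p.v_rest, p.v_threshold, p.gain_k,
        p.recovery_rate_a, p.recovery_coupling_b, p.reset_c,
        p.adaptation_increment_d, p.v_peak,
        float(input_current), float(dt), int(round(duration_ms / dt)),
    )
    if not np.all(np.isfinite(times)):
        raise IntegrationError("integration diverged")
    return SpikeTrain(0, times)


def simulate_qif(
    params: QIFParams,
    input_current: float,
    duration_ms: float,
    dt: float = DT_DEFAULT,
    v0: float | None = None,
    seed: int = 0,
) -> SpikeTrain:
    """Simulate one QIF neuron under constant current (plus optional noise)."""
    if dt <= 0 or duration_ms <= 0:
        raise ValueError("dt and duration must be positive")
    p = params
    times = _simulate_qif(
        p.v_rest if v0 is None else v0,
        p.membrane_time_constant, p.v_rest, p.v_critical, p.reset,
        p.v_peak, p.input_resistance, p.bias_current, p.noise_sd,
        float(input_current), float(dt), int(round(duration_ms / dt)),
        int(seed) % (2**31 - 1),
    )
    return SpikeTrain(0, times)


def qif_period(params: QIFParams, input_current: float = 0.0) -> float:
    """Closed-form inter-spike interval (ms) of a QIF pacemaker.

    Valid for constant suprathreshold total drive (intrinsic bias plus
    ``input_current`` above rheobase); returns ``inf`` for subthreshold
    drive.  Derived by integrating the quadratic membrane equation between
    reset and peak in the rescaled variable
    u = (v - (v_rest+v_critical)/2) / delta.
    """
    p = params
    delta = p.v_critical - p.v_rest
    total = p.bias_current + input_current
    q = p.input_resistance * total / delta - 0.25
    if q <= 0:
        return math.inf
    mid = 0.5 * (p.v_rest + p.v_critical)
    u_peak = (p.v_peak - mid) / delta
    u_reset = (p.reset - mid) / delta
    sq = math.sqrt(q)
    return p.membrane_time_constant / sq * (
        math.atan(u_peak / sq) - math.atan(u_reset / sq)
    )


def calibrate_bias_current(
    params: QIFParams,
    target_rate: float,
    tolerance: float = 0.1,
    duration_ms: float = 10_000.0,
    dt: float = DT_DEFAULT,
    max_bias: float = 500.0,
) -> float:
    """Bias current (pA) at which an isolated QIF neuron fires ``target_rate`` Hz.

    Deterministic bisection on the simulated 10 s firing rate (noise is
    ignored during calibration).  ``target_rate`` 0 returns 0 pA, which is
    subthreshold by construction.
    """
    if target_rate < 0:
        raise ValueError("target_rate must be non-negative")
    if target_rate == 0:
        return 0.0
    quiet = replace(params, noise_sd=0.0)

    def rate(bias: float) -> float:
        train = simulate_qif(replace(quiet, bias_current=bias), 0.0,
                             duration_ms, dt)
        return train.rate(duration_ms)

    lo, hi = 0.0, max_bias
    if rate(hi) < target_rate:
        raise CalibrationError(
            f"target {target_rate} Hz unreachable below {max_bias} pA"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target_rate) <= 0.5 * tolerance:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    final = 0.5 * (lo + hi)
    if abs(rate(final) - target_rate) > tolerance:
        raise CalibrationError("bisection did not converge to tolerance")
    return final
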