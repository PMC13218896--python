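"""Extracellular dopamine concentration readout.

Spike trains of the DA population are converted to a concentration trace
by an impulse-release / first-order-clearance kernel: every spike releases
a fixed increment of DA which is cleared exponentially with a regional
time constant.  Two regional kernels ship as defaults: a fast accumbens
kernel (sub-second clearance, the fast-scan voltammetry regime) and a slow
frontal-cortex kernel, whose clearance is set so that a single phasic
burst keeps cortical DA measurably above baseline for tens of minutes.
Michaelis-Menten reuptake is available as an alternative clearance mode.

``delta_da`` is the reward-prediction-error readout: mean concentration in
a response window following an RPE event minus the mean in a pre-event
baseline window.  ``rpe_response_curve`` maps RPE magnitude to mean
concentration change across seeds, the curve that steepens when agency is
raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .circuit import NetworkConfig, RPEEvent, SimulationRecording, build_network
from .neurons import SpikeTrain

__all__ = [
    "DAKernelParams",
    "DATrace",
    "NACC_KERNEL",
    "CORTEX_KERNEL",
    "spikes_to_concentration",
    "delta_da",
    "RPECurve",
    "rpe_response_curve",
    "excess_duration",
    "positive_slope",
    "negative_slope",
]


@dataclass(frozen=True)
class DAKernelParams:
    """Release/clearance kernel of one target region.

    ``release_increment`` is the concentration step per spike (arbitrary
    concentration units), ``clearance_tau`` the exponential clearance time
    constant in seconds.  ``detection_epsilon`` (fraction of baseline)
    defines when the trace counts as "above baseline".
    """

    release_increment: float
    clearance_tau: float       # s
    baseline: float
    region: str
    clearance: str = "exponential"      # or "michaelis_menten"
    vmax: float = 0.0          # a.u./s, Michaelis-Menten only
    km: float = 1.0            # a.u., Michaelis-Menten only
    detection_epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.release_increment <= 0 or self.clearance_tau <= 0:
            raise ValueError("release_increment and clearance_tau must be > 0")
        if self.clearance not in ("exponential", "michaelis_menten"):
            raise ValueError("unknown clearance mode")


# fast accumbens kernel (sub-second clearance)
NACC_KERNEL = DAKernelParams(release_increment=1.0, clearance_tau=0.2,
                             baseline=0.0, region="NAcc")
# slow cortical kernel: one ~20-spike phasic burst stays above the
# detection threshold for 20-30 simulated minutes
CORTEX_KERNEL = DAKernelParams(release_increment=0.2, clearance_tau=400.0,
                               baseline=10.0, region="cortex")


@dataclass(frozen=True)
class DATrace:
    times: np.ndarray          # s
    concentration: np.ndarray  # a.u.
    region: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentration", c)
        if t.shape != c.shape:
            raise ValueError("times and concentration must match in length")
        if c.size and c.min() < -1e-12:
            raise ValueError("concentration must be non-negative")

    def mean_in(self, t0: float, t1: float) -> float:
        sel = (self.times >= t0) & (self.times < t1)
        if not np.any(sel):
            raise ValueError("window contains no samples")
        return float(self.concentration[sel].mean())


@njit(cache=True)
def _amp_after_events(events_s, tau):
    """Summed kernel amplitude immediately after each event."""
    n = events_s.size
    amp = np.empty(n)
    a = 0.0
    prev = 0.0
    for i in range(n):
        a = a * np.exp(-(events_s[i] - prev) / tau) + 1.0
        amp[i] = a
        prev = events_s[i]
    return amp


def spikes_to_concentration(
    da_spike_trains: list[SpikeTrain] | SpikeTrain,
    kernel: DAKernelParams,
    resolution: float = 0.001,
    duration_s: float | None = None,
) -> DATrace:
    """Concentration trace from population spike trains.

    Exponential mode is evaluated exactly on the grid:
    ``c(t) = baseline + sum_spikes inc * exp(-(t - t_s)/tau)``.
    Michaelis-Menten mode integrates ``dc/dt = -vmax (c-b)/(km + (c-b))``
    between release impulses on the grid.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    trains = [da_spike_trains] if isinstance(da_spike_trains, SpikeTrain) \
        else list(da_spike_trains)
    all_ms = np.concatenate([t.spike_times for t in trains]) \
        if trains else np.empty(0)
    for t in trains:
        if t.spike_times.size and np.any(np.diff(t.spike_times) <= 0):
            raise ValueError("spike times must be sorted")
    events = np.sort(all_ms) * 1e-3  # s
    if duration_s is None:
        duration_s = float(events[-1]) + 10 * kernel.clearance_tau \
            if events.size else 1.0
    times = np.arange(0.0, duration_s, resolution)

    if kernel.clearance == "exponential":
        conc = np.full_like(times, kernel.baseline)
        if events.size:
            amp = _amp_after_events(events, kernel.clearance_tau)
            idx = np.searchsorted(events, times, side="right") - 1
            has = idx >= 0
            conc[has] += (kernel.release_increment * amp[idx[has]]
                          * np.exp(-(times[has] - events[idx[has]])
                                   / kernel.clearance_tau))
    else:
        conc = np.empty_like(times)
        c = kernel.baseline
        counts = np.histogram(events, bins=np.append(times, duration_s))[0]
        for j in range(times.size):
            c += kernel.release_increment * counts[j]
            excess = max(c - kernel.baseline, 0.0)
            c -= resolution * kernel.vmax * excess / (kernel.km + excess)
            c = max(c, kernel.baseline)
            conc[j] = c
    return DATrace(times, conc, kernel.region)


def delta_da(
    recording: SimulationRecording,
    event: RPEEvent,
    kernel: DAKernelParams = NACC_KERNEL,
    baseline_window: float = 1.0,
    response_window: float = 0.7,
    resolution: float = 0.001,
) -> float:
    """Mean concentration in the response window minus the pre-event
    baseline window (both in seconds; response starts at event onset)."""
    if baseline_window <= 0 or response_window <= 0:
        raise ValueError("windows must have positive length")
    onset_s = event.onset * 1e-3
    t0 = onset_s - baseline_window
    t1 = onset_s + response_window
    if t0 < 0:
        raise ValueError("baseline window precedes the recording")
    if t1 > recording.duration * 1e-3 + 1e-9:
        raise ValueError("response window exceeds the recording")
    trace = spikes_to_concentration(
        recording.da_trains, kernel, resolution,
        duration_s=recording.duration * 1e-3,
    )
    return trace.mean_in(onset_s, t1) - trace.mean_in(t0, onset_s)


@dataclass
class RPECurve:
    """Mean concentration response per RPE magnitude, across seeds."""

    agency: float
    deltas: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    samples: np.ndarray        # (n_seeds, n_deltas)

    def as_rows(self) -> list[tuple[float, float, float, int]]:
        n = self.samples.shape[0]
        return [(float(d), float(m), float(s), n)
                for d, m, s in zip(self.deltas, self.mean, self.se)]


def rpe_response_curve(
    agency_level: float,
    delta_grid: np.ndarray | list[float],
    n_seeds: int = 20,
    config: NetworkConfig | None = None,
    kernel: DAKernelParams = NACC_KERNEL,
    base_seed: int = 0,
) -> RPECurve:
    """One circuit run per (delta, seed); event at 3 s after a 2 s burn-in,
    response window covering the event and its decay."""
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    config = config or NetworkConfig()
    deltas = np.asarray(delta_grid, dtype=float)
    onset, ev_dur, total = 3000.0, 200.0, 4000.0
    samples = np.empty((n_seeds, deltas.size))
    for s in range(n_seeds):
        net = build_network(replace(config, seed=base_seed + s))
        for j, d in enumerate(deltas):
            ev = RPEEvent(onset=onset, delta=float(d), duration=ev_dur)
            rec = net.run(agency_level, (ev,) if d != 0 else (),
                          seed=base_seed + 1000 + s, duration=total)
            samples[s, j] = delta_da(rec, ev, kernel)
    mean = samples.mean(axis=0)
    se = samples.std(axis=0, ddof=1) / np.sqrt(n_seeds)
    return RPECurve(agency_level, deltas, mean, se, samples)


def positive_slope(curve: RPECurve) -> tuple[float, float]:
    """Least-squares slope (and its SE across seeds) over delta >= 0."""
    return _side_slope(curve, curve.deltas >= 0)


def negative_slope(curve: RPECurve) -> tuple[float, float]:
    return _side_slope(curve, curve.deltas <= 0)


def _side_slope(curve: RPECurve, sel: np.ndarray) -> tuple[float, float]:
    x = curve.deltas[sel]
    if x.size < 2:
        raise ValueError("need at least two grid points on this side")
    per_seed = np.array([np.polyfit(x, row[sel], 1)[0]
                         for row in curve.samples])
    return float(per_seed.mean()), \
        float(per_seed.std(ddof=1) / np.sqrt(per_seed.size))


def excess_duration(
    trace: DATrace,
    reference: DATrace,
    threshold: float,
) -> float:
    """Total time (s) the trace exceeds the reference by ``threshold``.

    Used for the cortical contract: the reference is the same simulation
    without the injected burst, so the difference isolates the burst's
    contribution.
    """
    if trace.times.size != reference.times.size:
        raise ValueError("traces must share a time grid")
    above = (trace.concentration - reference.concentration) > threshold
    if trace.times.size < 2:
        return 0.0
    dt = float(trace.times[1] - trace.times[0])
    return float(np.sum(above) * dt)
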