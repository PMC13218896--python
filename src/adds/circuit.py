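"""The agency-disinhibition circuit.

Wiring (fixed by anatomy): an agency-scaled ventral-subiculum (vSub) drive
excites nucleus-accumbens MSNs; the accumbens inhibits the ventral pallidum
(VP); the tonically active pallidum inhibits the VTA dopamine (DA)
population.  Because pallidal neurons fire tonically at ~7 Hz while MSNs
are near-silent, a share of the DA population is held silent by pallidal
inhibition at rest; raising agency excites the accumbens, suppresses the
pallidum, and releases DA neurons from inhibition (disinhibition).
Reward-prediction errors reach the DA population through two drive nodes:
the PPTN (excitatory, positive errors) and the RMTN (inhibitory, negative
errors).  A small configurable fraction of DA neurons is
"aversive-responding" and receives the RMTN drive with excitatory sign.

At any instant each DA neuron is in one of three states — silent (no
spiking, held down by the pallidum), tonic (pacemaker firing), or phasic
(bursting in response to the PPTN) — classified by
:func:`classify_da_states`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import engine
from .neurons import (
    DA_DEFAULTS,
    MSN_DEFAULTS,
    VP_DEFAULTS,
    IzhikevichParams,
    QIFParams,
    SpikeTrain,
    calibrate_bias_current,
)

__all__ = [
    "PopulationSpec",
    "ProjectionSpec",
    "AgencyInput",
    "RPEEvent",
    "NetworkConfig",
    "Network",
    "SimulationRecording",
    "build_network",
    "run_simulation",
    "classify_da_states",
    "detect_bursts",
    "fraction_active",
    "calibrate_vp_da_weight",
    "ConfigError",
    "SILENT",
    "TONIC",
    "PHASIC",
]

SILENT, TONIC, PHASIC = "silent", "tonic", "phasic"

# sign of each projection is fixed by the anatomy
_PROJECTION_SIGNS = {
    ("vSub", "NAcc"): +1,
    ("NAcc", "VP"): -1,
    ("VP", "VTA_DA"): -1,
    ("PPTN", "VTA_DA"): +1,
    ("RMTN", "VTA_DA"): -1,
}


class ConfigError(ValueError):
    """Invalid network configuration."""


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    model: IzhikevichParams | QIFParams

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ConfigError("population size must be >= 1")


@dataclass(frozen=True)
class ProjectionSpec:
    source: str
    target: str
    sign: int
    connection_probability: float
    weight: float        # pA per presynaptic spike
    synaptic_tau: float  # ms
    delay: float         # ms

    def __post_init__(self) -> None:
        expected = _PROJECTION_SIGNS.get((self.source, self.target))
        if expected is None:
            raise ConfigError(
                f"unknown projection {self.source}->{self.target}"
            )
        if self.sign != expected:
            raise ConfigError(
                f"projection {self.source}->{self.target} has anatomical "
                f"sign {expected:+d}"
            )
        if not 0.0 <= self.connection_probability <= 1.0:
            raise ConfigError("connection_probability must be in [0, 1]")
        if self.weight < 0 or self.synaptic_tau <= 0 or self.delay < 0:
            raise ConfigError("weight >= 0, tau > 0, delay >= 0 required")


@dataclass(frozen=True)
class AgencyInput:
    """Piecewise-constant agency schedule A(t), A in [0, 1].

    ``steps`` is a sequence of (onset_ms, level) pairs; the first onset
    must be 0 and onsets must increase.
    """

    steps: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.steps or self.steps[0][0] != 0.0:
            raise ConfigError("agency schedule must start at t=0")
        onsets = [t for t, _ in self.steps]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ConfigError("agency onsets must be strictly increasing")
        for _, a in self.steps:
            if not 0.0 <= a <= 1.0:
                raise ConfigError("agency level must be in [0, 1]")

    @classmethod
    def constant(cls, level: float) -> "AgencyInput":
        return cls(steps=((0.0, float(level)),))

    def sample(self, times_ms: np.ndarray) -> np.ndarray:
        onsets = np.array([t for t, _ in self.steps])
        levels = np.array([a for _, a in self.steps])
        idx = np.searchsorted(onsets, times_ms, side="right") - 1
        return levels[idx]


@dataclass(frozen=True)
class RPEEvent:
    """A reward-prediction-error episode: obtained minus expected value,
    scaled to [-1, 1], driving the PPTN (delta > 0) or RMTN (delta < 0)
    for ``duration`` ms from ``onset``."""

    onset: float
    delta: float
    duration: float = 200.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("event duration must be positive")
        if not -1.0 <= self.delta <= 1.0:
            raise ConfigError("delta must be in [-1, 1]")
        if self.onset < 0:
            raise ConfigError("onset must be non-negative")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class NetworkConfig:
    """Everything that determines a simulation, including the wiring seed."""

    n_nacc: int = 100
    n_vp: int = 100
    n_da: int = 100
    msn_params: IzhikevichParams = MSN_DEFAULTS
    vp_params: QIFParams = VP_DEFAULTS
    da_params: QIFParams = replace(DA_DEFAULTS, noise_sd=25.0)
    vp_target_rate: float = 7.0      # Hz, intrinsic pallidal pacemaker
    da_target_rate: float = 4.5      # Hz, intrinsic DA pacemaker
    connection_probability: float = 0.25
    p_vp_da: float = 0.009           # sparse, strong pallidal inhibition
    da_gaba_reversal: float = -75.0  # mV
    da_nmda_mg: float = 1.0          # Mg-block strength of the PPTN NMDA gate
    # synaptic strengths, pA per presynaptic spike / drive event
    w_vsub: float = 250.0
    w_nacc_vp: float = 1.5
    w_vp_da: float = 8.0             # nS per spike (GABA conductance)
    w_pptn: float = 10.0
    w_rmtn: float = 10.0
    weight_jitter: float = 0.5       # +- fractional spread of VP->DA weights
    tau_vsub: float = 5.0
    tau_nacc_vp: float = 10.0
    tau_vp_da: float = 20.0
    tau_pptn: float = 10.0
    tau_rmtn: float = 10.0
    delay_ms: float = 1.0
    # drive encodings
    vsub_rate_max: float = 40.0      # Hz per afferent at A = 1
    n_vsub_afferents: int = 10       # afferents per MSN
    pptn_rate_max: float = 10_000.0  # aggregate Hz per DA neuron at delta = 1
    rmtn_rate_max: float = 120.0
    f_aversive: float = 0.08         # fraction of aversive-responding DA cells
    aversive_gain: float = 1.0
    da_bias_sd: float = 6.0          # pA spread of DA pacemaker bias across cells
    msn_gain_spread: float = 0.5     # lognormal sigma of per-MSN afferent gain
    # agency operating points
    a_control: float = 0.35
    a_high: float = 0.85
    # integration
    dt: float = 0.5                  # ms
    duration: float = 12_000.0       # ms
    burn_in: float = 2_000.0         # ms discarded by protocol analyses
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_nacc, self.n_vp, self.n_da) < 1:
            raise ConfigError("population sizes must be >= 1")
        if not 0.0 <= self.connection_probability <= 1.0:
            raise ConfigError("connection_probability must be in [0, 1]")
        if not 0.0 <= self.f_aversive <= 0.14:
            raise ConfigError("f_aversive outside the plausible 0-14% range")
        if self.dt <= 0 or self.duration <= 0:
            raise ConfigError("dt and duration must be positive")

    @property
    def populations(self) -> tuple[PopulationSpec, ...]:
        return (
            PopulationSpec("NAcc", self.n_nacc, self.msn_params),
            PopulationSpec("VP", self.n_vp, self.vp_params),
            PopulationSpec("VTA_DA", self.n_da, self.da_params),
        )

    @property
    def projections(self) -> tuple[ProjectionSpec, ...]:
        p = self.connection_probability
        return (
            ProjectionSpec("vSub", "NAcc", +1, 1.0, self.w_vsub,
                           self.tau_vsub, 0.0),
            ProjectionSpec("NAcc", "VP", -1, p, self.w_nacc_vp,
                           self.tau_nacc_vp, self.delay_ms),
            ProjectionSpec("VP", "VTA_DA", -1, self.p_vp_da, self.w_vp_da,
                           self.tau_vp_da, self.delay_ms),
            ProjectionSpec("PPTN", "VTA_DA", +1, 1.0, self.w_pptn,
                           self.tau_pptn, 0.0),
            ProjectionSpec("RMTN", "VTA_DA", -1, 1.0, self.w_rmtn,
                           self.tau_rmtn, 0.0),
        )


@dataclass
class SimulationRecording:
    """Full output of one circuit run."""

    config: NetworkConfig
    seed: int
    duration: float
    dt: float
    spikes: dict[str, list[SpikeTrain]]
    drive_rates: dict[str, np.ndarray]  # per-step aggregate Hz per target

    @property
    def da_trains(self) -> list[SpikeTrain]:
        return self.spikes["VTA_DA"]

    def population_rate(self, name: str, t_start: float = 0.0,
                        t_end: float | None = None) -> float:
        """Mean per-neuron firing rate (Hz) of a population in a window."""
        t_end = self.duration if t_end is None else t_end
        trains = self.spikes[name]
        n = sum(
            int(np.sum((tr.spike_times >= t_start) & (tr.spike_times < t_end)))
            for tr in trains
        )
        return 1000.0 * n / (len(trains) * (t_end - t_start))

    def to_csv(self, directory: str | Path) -> None:
        """Write spikes as CSV (population, neuron_id, time_ms) plus a JSON
        summary embedding seed and key config values."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for pop, trains in self.spikes.items():
            for tr in trains:
                for t in tr.spike_times:
                    rows.append((pop, tr.neuron_id, t))
        pd.DataFrame(rows, columns=["population", "neuron_id", "time_ms"]).to_csv(
            directory / "spikes.csv", index=False
        )
        summary = {
            "seed": self.seed,
            "duration_ms": self.duration,
            "dt_ms": self.dt,
            "populations": {k: len(v) for k, v in self.spikes.items()},
        }
        (directory / "summary.json").write_text(json.dumps(summary, indent=2))


@lru_cache(maxsize=32)
def _calibrated_bias(params: QIFParams, target: float, dt: float) -> float:
    return calibrate_bias_current(params, target, dt=dt)


class Network:
    """A wired instance of the circuit; call :meth:`run`."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        c = config
        rng = np.random.default_rng(c.seed)
        mask_nv = rng.random((c.n_vp, c.n_nacc)) < c.connection_probability
        self.W_nacc_vp = mask_nv * c.w_nacc_vp
        mask_vd = rng.random((c.n_da, c.n_vp)) < c.p_vp_da
        jitter = rng.uniform(1.0 - c.weight_jitter, 1.0 + c.weight_jitter,
                             size=(c.n_da, c.n_vp))
        self.W_vp_da = mask_vd * c.w_vp_da * jitter
        n_av = int(round(c.f_aversive * c.n_da))
        av = np.zeros(c.n_da, dtype=np.bool_)
        av[rng.choice(c.n_da, size=n_av, replace=False)] = True
        self.aversive = av
        self.vp_bias = _calibrated_bias(
            replace(c.vp_params, noise_sd=0.0), c.vp_target_rate, c.dt
        )
        # heterogeneous pacemaker drive: DA tonic rates vary across cells,
        # which grades the silencing threshold across the population
        base = _calibrated_bias(
            replace(c.da_params, noise_sd=0.0), c.da_target_rate, c.dt
        )
        self.da_bias = base + rng.normal(0.0, c.da_bias_sd, c.n_da)
        # per-MSN afferent gain (unit mean, lognormal): spreads recruitment
        # thresholds so the population responds gradually to agency
        sig = c.msn_gain_spread
        self.msn_gain = rng.lognormal(-0.5 * sig * sig, sig, c.n_nacc)

    def run(
        self,
        agency: AgencyInput | float,
        rpe_events: tuple[RPEEvent, ...] = (),
        seed: int = 0,
        duration: float | None = None,
        pptn_background_rate: float = 0.0,
    ) -> SimulationRecording:
        """Simulate the wired network.

        ``agency`` scales the vSub drive (rate = vsub_rate_max * A per
        afferent); each RPE event adds a PPTN (delta > 0) or RMTN
        (delta < 0) Poisson drive for its duration.
        ``pptn_background_rate`` (aggregate Hz per DA neuron) models
        sustained PPTN activation, as in the activation protocol.
        """
        c = self.config
        if isinstance(agency, (int, float)):
            agency = AgencyInput.constant(agency)
        duration = c.duration if duration is None else float(duration)
        n_steps = int(round(duration / c.dt))
        times = np.arange(n_steps) * c.dt

        events = sorted(rpe_events, key=lambda e: e.onset)
        for a, b in zip(events, events[1:]):
            if b.onset < a.offset:
                raise ConfigError("RPE events must not overlap")
        for e in events:
            if e.offset > duration:
                raise ConfigError("RPE event extends beyond duration")

        vsub_rate = (c.vsub_rate_max * c.n_vsub_afferents
                     * agency.sample(times))
        pptn_rate = np.full(n_steps, float(pptn_background_rate))
        rmtn_rate = np.zeros(n_steps)
        for e in events:
            inside = (times >= e.onset) & (times < e.offset)
            if e.delta > 0:
                pptn_rate[inside] += c.pptn_rate_max * e.delta
            elif e.delta < 0:
                rmtn_rate[inside] += c.rmtn_rate_max * (-e.delta)

        m, v, d = c.msn_params, c.vp_params, c.da_params
        delay_steps = max(1, int(round(c.delay_ms / c.dt)))
        sp1, sp2, sp3 = engine.run_network(
            int(seed) % (2**31 - 1), n_steps, c.dt,
            m.capacitance, m.v_rest, m.v_threshold, m.gain_k,
            m.recovery_rate_a, m.recovery_coupling_b, m.reset_c,
            m.adaptation_increment_d, m.v_peak, c.n_nacc,
            v.membrane_time_constant, v.v_rest, v.v_critical, v.reset,
            v.v_peak, v.input_resistance, self.vp_bias, v.noise_sd, c.n_vp,
            d.membrane_time_constant, d.v_rest, d.v_critical, d.reset,
            d.v_peak, d.input_resistance, self.da_bias, d.noise_sd, c.n_da,
            self.W_nacc_vp, c.tau_nacc_vp, delay_steps,
            self.W_vp_da, c.tau_vp_da, delay_steps, c.da_gaba_reversal,
            c.da_nmda_mg,
            vsub_rate, c.w_vsub * self.msn_gain, c.tau_vsub,
            pptn_rate, c.w_pptn, c.tau_pptn,
            rmtn_rate, c.w_rmtn, c.tau_rmtn,
            self.aversive, c.aversive_gain,
        )

        def to_trains(sp: np.ndarray) -> list[SpikeTrain]:
            out = []
            for i in range(sp.shape[1]):
                steps = np.nonzero(sp[:, i])[0]
                out.append(SpikeTrain(i, (steps + 1) * c.dt))
            return out

        return SimulationRecording(
            config=c, seed=int(seed), duration=duration, dt=c.dt,
            spikes={"NAcc": to_trains(sp1), "VP": to_trains(sp2),
                    "VTA_DA": to_trains(sp3)},
            drive_rates={"vSub": vsub_rate, "PPTN": pptn_rate,
                         "RMTN": rmtn_rate},
        )


def build_network(config: NetworkConfig) -> Network:
    """Wire the circuit deterministically from ``config.seed``."""
    return Network(config)


def run_simulation(
    network: Network,
    agency: AgencyInput | float,
    rpe_events: tuple[RPEEvent, ...] = (),
    seed: int = 0,
    **kwargs,
) -> SimulationRecording:
    return network.run(agency, rpe_events, seed=seed, **kwargs)


def detect_bursts(
    train: SpikeTrain,
    burst_isi_on: float = 80.0,
    burst_isi_off: float = 160.0,
) -> list[tuple[float, float]]:
    """Burst episodes by the standard DA ISI convention: a burst starts
    with an inter-spike interval below ``burst_isi_on`` ms and ends at the
    first interval above ``burst_isi_off`` ms."""
    times = train.spike_times
    bursts: list[tuple[float, float]] = []
    start = None
    for a, b in zip(times, times[1:]):
        isi = b - a
        if start is None:
            if isi < burst_isi_on:
                start = a
        elif isi > burst_isi_off:
            bursts.append((start, a))
            start = None
    if start is not None:
        bursts.append((start, times[-1]))
    return bursts


def classify_da_states(
    recording: SimulationRecording,
    window: float = 10_000.0,
    tonic_threshold: float = 0.5,
    burst_isi_on: float = 80.0,
    burst_isi_off: float = 160.0,
    t_start: float | None = None,
) -> list[str]:
    """Label each DA neuron silent / tonic / phasic over an analysis window.

    The window is ``[t_start, t_start + window)``; by default the last
    ``window`` ms of the recording.  A neuron is silent when its window
    rate falls below ``tonic_threshold`` Hz (a neuron exactly at threshold
    counts as tonic), phasic when it emits at least one ISI burst, and
    tonic otherwise.
    """
    if window < 1000.0:
        raise ValueError("analysis window must be >= 1000 ms")
    trains = recording.da_trains
    if not trains:
        raise ValueError("recording holds no DA spike trains")
    t0 = recording.duration - window if t_start is None else t_start
    t1 = t0 + window
    if t0 < 0 or t1 > recording.duration + 1e-9:
        raise ValueError("analysis window outside the recording")
    labels = []
    for tr in trains:
        sel = (tr.spike_times >= t0) & (tr.spike_times < t1)
        sub = SpikeTrain(tr.neuron_id, tr.spike_times[sel])
        rate = 1000.0 * len(sub) / window
        if rate < tonic_threshold:
            labels.append(SILENT)
        elif detect_bursts(sub, burst_isi_on, burst_isi_off):
            labels.append(PHASIC)
        else:
            labels.append(TONIC)
    return labels


def fraction_active(labels: list[str]) -> float:
    """Fraction of DA neurons not silent (tonic or phasic)."""
    return sum(1 for s in labels if s != SILENT) / len(labels)


def calibrate_vp_da_weight(
    config: NetworkConfig,
    target_fraction: float = 0.5,
    n_seeds: int = 5,
    lo: float = 0.5,
    hi: float = 30.0,
    max_iter: int = 12,
    tol: float = 0.03,
) -> float:
    """Pallidum-to-DA weight at which the control-agency network leaves
    ``target_fraction`` of DA neurons active.

    Bisection on the mean active fraction across ``n_seeds`` wiring/run
    seeds.  The active fraction decreases in the weight, so plain
    bisection applies.  Used to pin the package default; also usable from
    tests with small populations.
    """

    def frac(w: float) -> float:
        vals = []
        for s in range(n_seeds):
            cfg = replace(config, w_vp_da=w, seed=config.seed + s)
            rec = build_network(cfg).run(cfg.a_control, seed=1000 + s)
            win = cfg.duration - cfg.burn_in
            vals.append(fraction_active(
                classify_da_states(rec, window=win)))
        return float(np.mean(vals))

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target_fraction) <= tol:
            return mid
        if f > target_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
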