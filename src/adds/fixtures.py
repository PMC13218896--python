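"""Deterministic spike-train generators for tests and worked examples."""

from __future__ import annotations

import numpy as np

from .neurons import SpikeTrain

__all__ = ["generate_fixture_spiketrains"]


def generate_fixture_spiketrains(
    kind: str,
    rate: float,
    duration_ms: float,
    seed: int = 0,
    n_trains: int = 1,
    burst_time_ms: float | None = None,
    burst_spikes: int = 20,
    burst_isi_ms: float = 15.0,
) -> list[SpikeTrain]:
    """Synthetic spike trains: ``poisson``, ``regular`` or
    ``burst_injected``.

    ``regular`` places spikes at exact multiples of the period, so a 7 Hz
    train over 10 s holds exactly 70 spikes.  ``burst_injected`` takes the
    regular train and splices in one cluster of ``burst_spikes`` spikes at
    ``burst_time_ms`` (default: mid-recording) with ``burst_isi_ms``
    spacing, displacing any background spikes that would collide.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)

    def regular() -> np.ndarray:
        if rate == 0:
            return np.empty(0)
        period = 1000.0 / rate
        return np.arange(period, duration_ms + 1e-9, period)

    trains = []
    for i in range(n_trains):
        if kind == "poisson":
            if rate == 0:
                times = np.empty(0)
            else:
                n = rng.poisson(rate * duration_ms / 1000.0)
                times = np.sort(rng.uniform(0.0, duration_ms, n))
                times = times[np.insert(np.diff(times) > 0, 0, True)]
        elif kind == "regular":
            times = regular()
        elif kind == "burst_injected":
            t0 = duration_ms / 2 if burst_time_ms is None else burst_time_ms
            burst = t0 + burst_isi_ms * np.arange(burst_spikes)
            if burst[-1] > duration_ms:
                raise ValueError("burst extends beyond duration")
            base = regular()
            pad = burst_isi_ms
            keep = (base < burst[0] - pad) | (base > burst[-1] + pad)
            times = np.sort(np.concatenate([base[keep], burst]))
        else:
            raise ValueError(f"unknown fixture kind {kind!r}")
        trains.append(SpikeTrain(i, times))
    return trains
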