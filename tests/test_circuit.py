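"""Circuit wiring, simulation determinism, DA-state classification and
the disinhibition chain."""

from dataclasses import replace

import numpy as np
import pytest

from adds.circuit import (
    AgencyInput,
    ConfigError,
    NetworkConfig,
    ProjectionSpec,
    RPEEvent,
    build_network,
    classify_da_states,
    detect_bursts,
    fraction_active,
)
from adds.fixtures import generate_fixture_spiketrains
from adds.neurons import SpikeTrain


class TestBuild:
    def test_default_structure_three_populations_five_projections(
            self, default_config):
        assert len(default_config.populations) == 3
        assert len(default_config.projections) == 5
        signs = {(p.source, p.target): p.sign
                 for p in default_config.projections}
        assert signs[("vSub", "NAcc")] == +1
        assert signs[("NAcc", "VP")] == -1
        assert signs[("VP", "VTA_DA")] == -1
        assert signs[("PPTN", "VTA_DA")] == +1
        assert signs[("RMTN", "VTA_DA")] == -1

    def test_anatomical_sign_is_enforced(self):
        with pytest.raises(ConfigError):
            ProjectionSpec("VP", "VTA_DA", +1, 0.1, 1.0, 10.0, 1.0)
        with pytest.raises(ConfigError):
            ProjectionSpec("VP", "NAcc", -1, 0.1, 1.0, 10.0, 1.0)

    def test_same_seed_gives_identical_wiring(self, small_config):
        a = build_network(small_config)
        b = build_network(small_config)
        c = build_network(replace(small_config, seed=small_config.seed + 1))
        assert np.array_equal(a.W_vp_da, b.W_vp_da)
        assert np.array_equal(a.W_nacc_vp, b.W_nacc_vp)
        assert not np.array_equal(a.W_vp_da, c.W_vp_da)

    def test_invalid_population_size_rejected(self):
        with pytest.raises(ConfigError):
            NetworkConfig(n_da=0)


class TestRun:
    def test_identical_seeds_give_identical_recordings(self, small_config):
        net = build_network(small_config)
        r1 = net.run(0.5, seed=3)
        r2 = net.run(0.5, seed=3)
        for pop in ("NAcc", "VP", "VTA_DA"):
            for a, b in zip(r1.spikes[pop], r2.spikes[pop]):
                assert np.array_equal(a.spike_times, b.spike_times)

    def test_unconnected_populations_keep_intrinsic_rates(self, small_config):
        cfg = replace(small_config, connection_probability=0.0, p_vp_da=0.0,
                      da_bias_sd=0.0, duration=10_000.0)
        net = build_network(cfg)
        rec = net.run(0.0, seed=1)
        assert rec.population_rate("VP") == pytest.approx(7.0, abs=0.15)
        assert rec.population_rate("NAcc") == 0.0

    def test_event_outside_duration_rejected(self, small_config):
        net = build_network(small_config)
        with pytest.raises(ConfigError):
            net.run(0.5, (RPEEvent(onset=small_config.duration, delta=0.5),),
                    seed=0)

    def test_overlapping_events_rejected(self, small_config):
        net = build_network(small_config)
        events = (RPEEvent(onset=1000.0, delta=0.5),
                  RPEEvent(onset=1100.0, delta=-0.5))
        with pytest.raises(ConfigError):
            net.run(0.5, events, seed=0)

    def test_vp_lesion_releases_dopamine_neurons(self, default_config):
        """With no drives at all, tonic pallidal firing silences roughly
        half the DA cells relative to a VP-lesioned network (a few cells
        stay silent either way through pacemaker-bias heterogeneity)."""
        fi, fl = [], []
        for s in (3, 5, 7):
            cfg = replace(default_config, seed=s)
            intact = build_network(cfg).run(0.0, seed=5)
            lesion = build_network(replace(cfg, w_vp_da=0.0)).run(0.0, seed=5)
            fi.append(fraction_active(classify_da_states(intact)))
            fl.append(fraction_active(classify_da_states(lesion)))
        f_intact, f_lesion = np.mean(fi), np.mean(fl)
        assert f_lesion > 0.85
        assert f_intact < 0.62 * f_lesion

    def test_agency_raises_nacc_and_suppresses_vp(self, default_config):
        net = build_network(default_config)
        lo = net.run(default_config.a_control, seed=2)
        hi = net.run(default_config.a_high, seed=2)
        t0 = default_config.burn_in
        assert hi.population_rate("NAcc", t0) > lo.population_rate("NAcc", t0)
        assert hi.population_rate("VP", t0) < lo.population_rate("VP", t0)
        f_lo = fraction_active(classify_da_states(lo))
        f_hi = fraction_active(classify_da_states(hi))
        assert f_hi > f_lo


class TestAgencyInput:
    def test_constant_schedule(self):
        a = AgencyInput.constant(0.4)
        assert np.all(a.sample(np.array([0.0, 500.0])) == 0.4)

    def test_piecewise_schedule_samples_correctly(self):
        a = AgencyInput(steps=((0.0, 0.2), (1000.0, 0.8)))
        np.testing.assert_allclose(
            a.sample(np.array([0.0, 999.0, 1000.0, 2000.0])),
            [0.2, 0.2, 0.8, 0.8])

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ConfigError):
            AgencyInput.constant(1.5)
        with pytest.raises(ConfigError):
            AgencyInput(steps=((100.0, 0.5),))


class TestClassification:
    def _recording(self, trains, duration=12_000.0):
        from adds.circuit import SimulationRecording
        return SimulationRecording(
            config=NetworkConfig(), seed=0, duration=duration, dt=0.5,
            spikes={"NAcc": [], "VP": [], "VTA_DA": trains},
            drive_rates={},
        )

    def test_no_spikes_is_silent(self):
        rec = self._recording([SpikeTrain(0, [])])
        assert classify_da_states(rec) == ["silent"]

    def test_regular_pacemaker_is_tonic(self):
        train = generate_fixture_spiketrains("regular", 4.5, 12_000.0)[0]
        assert classify_da_states(self._recording([train])) == ["tonic"]

    def test_injected_isi_cluster_is_phasic(self):
        train = generate_fixture_spiketrains(
            "burst_injected", 4.5, 12_000.0, burst_time_ms=8_000.0,
            burst_spikes=3, burst_isi_ms=60.0)[0]
        assert classify_da_states(self._recording([train])) == ["phasic"]
        assert detect_bursts(train)  # the cluster is found directly

    def test_rate_exactly_at_threshold_counts_as_tonic(self):
        # 5 spikes in a 10 s window at 0.5 Hz threshold
        times = 2000.0 + np.arange(5) * 2000.0
        rec = self._recording([SpikeTrain(0, times)])
        labels = classify_da_states(rec, tonic_threshold=0.5)
        assert labels == ["tonic"]

    def test_empty_recording_rejected(self):
        rec = self._recording([])
        with pytest.raises(ValueError):
            classify_da_states(rec)

    def test_window_shorter_than_one_second_rejected(self):
        rec = self._recording([SpikeTrain(0, [])])
        with pytest.raises(ValueError):
            classify_da_states(rec, window=500.0)


class TestChannelIndependence:
    def test_agency_changes_population_without_bursts(self, default_config):
        net = build_network(default_config)
        rec = net.run(default_config.a_high, seed=11)
        labels = classify_da_states(rec)
        assert "phasic" not in labels

    def test_positive_rpe_bursts_only_already_tonic_cells(self,
                                                          default_config):
        net = build_network(default_config)
        ev = RPEEvent(onset=3000.0, delta=1.0)
        quiet = net.run(default_config.a_control, (), seed=12,
                        duration=4000.0)
        driven = net.run(default_config.a_control, (ev,), seed=12,
                         duration=4000.0)
        active_before = [
            np.sum((t.spike_times >= 1000.0) & (t.spike_times < 3000.0)) / 2.0
            >= 0.5
            for t in quiet.da_trains
        ]
        burst_sil = burst_act = 0
        for train, active in zip(driven.da_trains, active_before):
            sel = train.spike_times[(train.spike_times >= 2950.0)
                                    & (train.spike_times < 3400.0)]
            if sel.size > 1 and np.any(np.diff(sel) < 80.0):
                if active:
                    burst_act += 1
                else:
                    burst_sil += 1
        assert burst_act > 0
        assert burst_sil == 0
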