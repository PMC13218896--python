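"""Shared fixtures.

The heavy multi-seed circuit experiments are session-scoped so that the
population-activity calibration, the activation-protocol dissociation and
the RPE-curve comparisons reuse the same simulations.
"""

from __future__ import annotations

import numpy as np
import pytest

from adds.circuit import NetworkConfig
from adds.da_signal import rpe_response_curve
from adds.protocols import ProtocolSettings, run_condition

N_SEEDS = 20


@pytest.fixture(scope="session")
def default_config() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture(scope="session")
def small_config() -> NetworkConfig:
    """Reduced network for structural/determinism tests."""
    return NetworkConfig(n_nacc=30, n_vp=30, n_da=30, duration=3000.0,
                         burn_in=1000.0)


@pytest.fixture(scope="session")
def protocol_settings() -> ProtocolSettings:
    return ProtocolSettings(n_seeds=N_SEEDS)


@pytest.fixture(scope="session")
def lodge_grace_results(default_config, protocol_settings):
    """All four activation conditions plus a disjoint control block,
    20 seeds each."""
    out = {}
    for cond in ("control", "vsub", "pptn", "both"):
        out[cond] = run_condition(cond, N_SEEDS, default_config,
                                  protocol_settings, base_seed=0)
    out["control2"] = run_condition("control", N_SEEDS, default_config,
                                    protocol_settings, base_seed=N_SEEDS)
    return out


@pytest.fixture(scope="session")
def agency_sweep_results(default_config, protocol_settings):
    from adds.protocols import agency_sweep
    return agency_sweep([0.2, 0.5, 0.8], N_SEEDS, default_config,
                        protocol_settings, base_seed=0)


@pytest.fixture(scope="session")
def rpe_curves(default_config):
    """Positive-side RPE response curves at control and high agency."""
    grid = [0.0, 0.5, 1.0]
    ctrl = rpe_response_curve(default_config.a_control, grid, N_SEEDS,
                              default_config, base_seed=0)
    high = rpe_response_curve(default_config.a_high, grid, N_SEEDS,
                              default_config, base_seed=0)
    return ctrl, high


@pytest.fixture(scope="session")
def full_rpe_curve_control(default_config):
    """Both-sided curve at control agency (fewer seeds; shape only)."""
    grid = [-1.0, -0.5, 0.0, 0.5, 1.0]
    return rpe_response_curve(default_config.a_control, grid, 8,
                              default_config, base_seed=0)
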