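"""Packaged in-silico experiments on the disinhibition circuit.

The central protocol replicates the classic activation experiment in
which the ventral subiculum (vSub), the pedunculopontine tegmental
nucleus (PPTN), or both are activated while two measures of the VTA DA
population are recorded: the percentage of tonically active (non-silent)
cells, and the mean firing rate of the currently active cells.  The
expected pattern is a double dissociation — vSub activation raises the
population measure but not the rate, PPTN activation raises the rate but
not the population measure, and co-activation raises both.

All protocols run one full circuit simulation per seed, discard a burn-in
period, and summarise across seeds with means, standard errors and
permutation tests against control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import (
    NetworkConfig,
    build_network,
    classify_da_states,
    fraction_active,
)

__all__ = [
    "ProtocolSettings",
    "ProtocolResult",
    "run_condition",
    "run_lodge_grace",
    "agency_sweep",
    "compare_to_control",
    "permutation_pvalue",
]

CONDITIONS = ("control", "vsub", "pptn", "both")


@dataclass(frozen=True)
class ProtocolSettings:
    """Shared knobs of the activation protocols."""

    n_seeds: int = 20
    pptn_activation_rate: float = 400.0   # aggregate Hz per DA neuron
    n_permutations: int = 10_000
    stat_seed: int = 0
    method: str = "permutation"           # or "welch"


@dataclass
class ProtocolResult:
    """Multi-seed summary of one condition."""

    condition: str
    seeds: list[int]
    percent_active: np.ndarray       # per-seed, %
    rate_active: np.ndarray          # per-seed, Hz (mean over active cells)
    p_vs_control: dict[str, float] = field(default_factory=dict)
    config_hash: str = ""

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    @property
    def percent_mean(self) -> float:
        return float(self.percent_active.mean())

    @property
    def percent_se(self) -> float:
        return float(self.percent_active.std(ddof=1) / np.sqrt(self.n_seeds))

    @property
    def rate_mean(self) -> float:
        return float(self.rate_active.mean())

    @property
    def rate_se(self) -> float:
        return float(self.rate_active.std(ddof=1) / np.sqrt(self.n_seeds))

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_seeds": self.n_seeds,
            "seeds": list(map(int, self.seeds)),
            "percent_active": {
                "mean": self.percent_mean, "se": self.percent_se,
                "per_seed": self.percent_active.tolist(),
            },
            "rate_active": {
                "mean": self.rate_mean, "se": self.rate_se,
                "per_seed": self.rate_active.tolist(),
            },
            "p_vs_control": self.p_vs_control,
            "config_hash": self.config_hash,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _config_hash(config: NetworkConfig) -> str:
    return sha256(repr(config).encode()).hexdigest()[:16]


def _measures(recording, config: NetworkConfig) -> tuple[float, float]:
    window = config.duration - config.burn_in
    labels = classify_da_states(recording, window=window,
                                t_start=config.burn_in)
    frac = fraction_active(labels)
    rates = []
    for train, lab in zip(recording.da_trains, labels):
        if lab == "silent":
            continue
        n = np.sum(train.spike_times >= config.burn_in)
        rates.append(1000.0 * n / window)
    rate = float(np.mean(rates)) if rates else 0.0
    return 100.0 * frac, rate


def run_condition(
    condition: str,
    n_seeds: int = 20,
    config: NetworkConfig | None = None,
    settings: ProtocolSettings | None = None,
    agency: float | None = None,
    base_seed: int = 0,
) -> ProtocolResult:
    """Run one activation condition across seeds.

    control: A_control, no RPE drive; vsub: A_high; pptn: A_control plus
    sustained PPTN drive; both: A_high plus sustained PPTN drive.  An
    explicit ``agency`` level overrides the condition's default (used by
    :func:`agency_sweep`).
    """
    config = config or NetworkConfig()
    settings = settings or ProtocolSettings(n_seeds=n_seeds)
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if agency is None:
        agency = config.a_high if condition in ("vsub", "both") \
            else config.a_control
    pptn_bg = settings.pptn_activation_rate \
        if condition in ("pptn", "both") else 0.0

    seeds = [base_seed + i for i in range(n_seeds)]
    pct = np.empty(n_seeds)
    rate = np.empty(n_seeds)
    for i, s in enumerate(seeds):
        net = build_network(replace(config, seed=s))
        rec = net.run(agency, seed=10_000 + s,
                      pptn_background_rate=pptn_bg)
        pct[i], rate[i] = _measures(rec, config)
    return ProtocolResult(condition, seeds, pct, rate,
                          config_hash=_config_hash(config))


def run_lodge_grace(
    condition: str,
    n_seeds: int = 20,
    config: NetworkConfig | None = None,
    settings: ProtocolSettings | None = None,
    base_seed: int = 0,
) -> ProtocolResult:
    """Activation protocol for one condition, with significance against a
    matched control run when the condition is not itself control."""
    if n_seeds < 10:
        raise ValueError("n_seeds must be >= 10 for significance testing")
    settings = settings or ProtocolSettings(n_seeds=n_seeds)
    result = run_condition(condition, n_seeds, config, settings,
                           base_seed=base_seed)
    if condition != "control":
        # disjoint seed block for the control comparison
        control = run_condition("control", n_seeds, config, settings,
                                base_seed=base_seed + n_seeds)
        result.p_vs_control = compare_to_control(result, control,
                                                 settings.method,
                                                 settings=settings)
    return result


def agency_sweep(
    levels,
    n_seeds: int = 20,
    config: NetworkConfig | None = None,
    settings: ProtocolSettings | None = None,
    base_seed: int = 0,
) -> list[ProtocolResult]:
    """Population-activity and rate measures at each agency level."""
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least two agency levels")
    out = []
    for a in levels:
        r = run_condition("control", n_seeds, config, settings,
                          agency=a, base_seed=base_seed)
        r.condition = f"A={a:g}"
        out.append(r)
    return out


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a difference in means.

    Monte-Carlo over group relabelings, with the +1 correction so that
    identical samples give exactly 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two values per group")
    rng = np.random.default_rng(seed)
    obs = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n = x.size
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(pooled)
        if abs(pooled[:n].mean() - pooled[n:].mean()) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def compare_to_control(
    result: ProtocolResult,
    control: ProtocolResult,
    method: str = "permutation",
    settings: ProtocolSettings | None = None,
) -> dict[str, float]:
    """Two-sided p-value per measure (percent active, active-cell rate)."""
    settings = settings or ProtocolSettings()
    out = {}
    for name, a, b in (
        ("percent_active", result.percent_active, control.percent_active),
        ("rate_active", result.rate_active, control.rate_active),
    ):
        if method == "permutation":
            out[name] = permutation_pvalue(a, b, settings.n_permutations,
                                           settings.stat_seed)
        elif method == "welch":
            out[name] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def results_to_csv(results: list[ProtocolResult], path: str | Path) -> None:
    rows = []
    for r in results:
        rows.append({
            "condition": r.condition,
            "n_seeds": r.n_seeds,
            "percent_active_mean": r.percent_mean,
            "percent_active_se": r.percent_se,
            "rate_active_mean": r.rate_mean,
            "rate_active_se": r.rate_se,
            "p_percent": r.p_vs_control.get("percent_active", np.nan),
            "p_rate": r.p_vs_control.get("rate_active", np.nan),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
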