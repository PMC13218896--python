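# adds

A spiking-circuit simulator of how the **sense of agency disinhibits the
midbrain dopamine system**, together with the neuroeconomic decision layer
that this dopamine state implies: agency-dependent utility, risk taking,
probability weighting and hyperbolic temporal discounting.

## Who this is for

Computational neuroscientists and decision scientists who want a runnable,
parameterised version of the agency-disinhibition account (ADDS: Agency
Disinhibits the Dopamine System): a ventral-subiculum → nucleus-accumbens →
ventral-pallidum → VTA chain in which raising a scalar agency signal
*A ∈ [0, 1]* releases dopamine (DA) neurons from tonic pallidal inhibition,
and reward-prediction errors (RPEs) drive phasic bursts and dips in the
released pool.

## The model in brief

**Circuit.** The accumbens is 100 Izhikevich medium spiny neurons (tonic
rate 0 Hz, up/down states); the pallidum and the VTA DA population are each
100 quadratic integrate-and-fire pacemakers with bias currents calibrated to
7 Hz and ≈4.5 Hz. Pallidal GABA conductances silence roughly half the DA
population under control agency (A = 0.35). An RPE event δ ∈ [−1, 1] drives
an NMDA-gated excitatory PPTN input (δ > 0) or an inhibitory RMTN input
(δ < 0) for 200 ms. At every instant each DA neuron is **silent**, **tonic**
or **phasic**.

**Readout.** Spikes convert to extracellular DA concentration through a
release-increment / exponential-clearance kernel — fast in the accumbens
(τ = 0.2 s), slow in frontal cortex (τ = 400 s, so one phasic burst stays
above baseline for 20–30 min).

**Decision layer.** Utility is two-part power with exponent 0.88,
calibrated so that under control conditions a gain of 79 has utility +50 and
a loss of 48 has utility −50. High agency multiplies gains by 1.38 and
losses by only 1.06, so the same gain becomes +69 while the loss moves to
−53. Choices maximise

  U = Σᵢ π(pᵢ) · u(xᵢ) · D(tᵢ),  D(t) = 1 / (1 + αt),

with π either the identity or a one-parameter inverse-S weight, and the
discount rate α optionally coupled to tonic DA through a U-shaped function
(minimum at a DA optimum — the dopamine-overdose logic).

## Worked example

```python
from adds import (AgencyContext, WORKED_GAMBLE, expected_utility,
                  accept_gamble, utility)

ctrl, high = AgencyContext.control(), AgencyContext.high()
print(utility(79, ctx=ctrl), utility(-48, ctx=ctrl))   # 50.0 -50.0
print(utility(79, ctx=high), utility(-48, ctx=high))   # 69.0 -53.0
print(expected_utility(WORKED_GAMBLE, ctx=ctrl))       # 0.0
print(expected_utility(WORKED_GAMBLE, ctx=high))       # 8.0
print(accept_gamble(WORKED_GAMBLE, ctx=high))          # accept
```

A decision maker indifferent to the 50/50 win-79/lose-48 coin toss under
control conditions strictly prefers it (EU = +8) when agency is high: the
asymmetric gain/loss amplification produces risk seeking.

Circuit side:

```python
from adds import NetworkConfig, build_network, classify_da_states, fraction_active

cfg = NetworkConfig()
net = build_network(cfg)
rec = net.run(cfg.a_control, seed=1)
print(fraction_active(classify_da_states(rec)))        # ~0.5
rec = net.run(cfg.a_high, seed=1)
print(fraction_active(classify_da_states(rec)))        # ~0.85
```

Raising agency roughly doubles the tonically active share of the DA
population without changing the firing rate of already-active cells — the
signature double dissociation probed by `adds lodge-grace`.

## Command line

```bash
adds decide --out runs/decide            # the worked gamble, both contexts
adds lodge-grace --condition vsub        # activation protocol, 20 seeds
adds rpe-curve --agency 0.85             # ΔDA vs RPE curve
adds discount-curve --alpha 0.1
adds simulate --agency 0.6 --rpe 3000 0.8
adds calibrate
```

Every run directory contains the resolved configuration, the seed and a
config hash, so results regenerate bit-identically.

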