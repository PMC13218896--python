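# Methods

## Scope

`adds` implements a computational account of how the sense of agency
modulates midbrain dopamine (DA) and, through it, economic choice. It has
two halves that can be used independently: a spiking circuit
(vSub → NAcc → VP → VTA with PPTN/RMTN prediction-error drives, plus a
DA-concentration readout) and a closed-form decision layer (prospect-theory
utility, weighted expected utility, hyperbolic discounting). The circuit
can feed the decision layer through a tonic-DA proxy, but the decision
layer is fully specified on its own.

## Neuron models

*Medium spiny neurons* (nucleus accumbens) use the two-variable Izhikevich
system with the striatal parameterisation C = 50 pF, v_rest = −80 mV,
v_threshold = −25 mV, k = 1, a = 0.01 /ms, b = −20 nS, c = −55 mV,
d = 150 pA, v_peak = 40 mV. Undriven they are exactly silent (the 0 Hz
tonic contract); under fluctuating synaptic input they show the up/down
membrane states characteristic of MSNs.

*Pallidal and DA neurons* use a quadratic integrate-and-fire (QIF) form

  τ dv/dt = (v − v_rest)(v − v_critical)/(v_critical − v_rest) + R·I,

with v_rest = −65, v_critical = −50, v_peak = 30, reset −65 mV and
R = 0.1 mV/pA. The inter-spike interval under constant drive has a closed
form (arctan integral), which the tests use as an analytic oracle. Bias
currents are calibrated by bisection on a simulated 10 s rate: 7 Hz for the
ventral pallidum, 4.5 Hz for DA cells (a literature-typical pacemaker rate;
configurable). DA cells additionally receive per-cell bias jitter
(sd 6 pA) and per-step current noise (sd 25 pA): both are needed so that
the silenced/active boundary is graded across the population rather than
all-or-none.

Integration is explicit Euler at dt = 0.5 ms. Halving dt changes a 10 s
pacemaker spike count by at most one spike; single-neuron rate accuracy of
2 % against a 100×-finer reference holds at dt = 0.1 ms, which is what the
precision tests use. A spike is stamped at the end of the step in which the
membrane crosses v_peak.

## Circuit wiring and calibration

Drives (vSub, PPTN, RMTN) are aggregate Poisson event sources per target
neuron; the LHb→RMTN chain is collapsed into the single RMTN drive. The
vSub rate is linear in agency: 40·A Hz per afferent, 10 afferents per MSN,
with a lognormal per-MSN gain spread (σ = 0.5). The spread is what makes
the *population* MSN response graded in A even though each MSN is strongly
threshold-like; without it the chain has a dead zone below control agency.

NAcc→VP is dense weak current inhibition (p = 0.25, 1.5 pA, τ = 10 ms).
VP→VTA is **sparse, strong GABA conductance** inhibition: connection
probability 0.009, 8 nS per spike, τ = 20 ms, reversal −75 mV. Sparseness
makes silencing roughly binary per cell (a cell with one pallidal afferent
is solidly silenced at the 7 Hz pallidal rate; an unconnected cell
pacemakes at its intrinsic rate), and the conductance form is divisive:
a silenced cell that is pushed toward threshold feels proportionally more
inhibitory current, so excitatory drive does not recruit it. Both features
were found necessary for the activation double dissociation below; dense
current-based inhibition made the active fraction all-or-none and let the
active-cell rate covary with agency.

PPTN input to DA cells is NMDA-like: the synaptic current is multiplied by
the Jahr–Stevens magnesium-block factor 1/(1 + Mg·e^(−0.062 v)) with
Mg = 1.0. Hyperpolarised (silenced) cells therefore barely feel it, while
pacemaking cells are boosted — mirroring the NMDA-infusion logic of the
activation experiments and preventing sustained PPTN drive from changing
the number of active cells. RMTN input is ordinary current-based
inhibition, present only during negative-RPE events; a configurable 8 % of
DA cells (within the empirical 3–14 % range for aversive-responding cells)
receive it with excitatory sign instead, which softens the negative limb
of the RPE response.

Under these defaults, control agency (A = 0.35) leaves ≈50 % of the DA
population tonically active; A_high = 0.85 raises this to ≈85 % while
leaving the mean rate of active cells statistically unchanged. The
calibration target (≈50 % at control) is prescribed; the weight that
achieves it can be re-derived with `circuit.calibrate_vp_da_weight`.

## DA-state classification

Per analysis window (default: the 10 s after a 2 s burn-in): silent if the
window rate is below 0.5 Hz (a cell exactly at threshold counts as tonic),
phasic if any ISI burst occurs (enter below 80 ms, exit above 160 ms — the
standard DA burst convention), otherwise tonic.

## Concentration readout

Concentration is baseline + Σ spikes release_increment·e^(−Δt/τ),
evaluated exactly on the output grid (amplitudes accumulate recursively
at event times, so no binning error). Michaelis–Menten reuptake is
available as an alternative clearance mode. Kernels: accumbens
(increment 1.0 a.u., τ = 0.2 s, baseline 0) and cortex (increment 0.2,
τ = 400 s, baseline 10). With the default 20-spike injected burst the
cortical excess stays above 1 % of baseline for ≈24 minutes, inside the
20–30 min physiological window; the burst's contribution is isolated by
subtracting the same simulation without the burst.

ΔDA for an RPE event is the mean concentration in a response window
(0.7 s from onset) minus the mean in a 1 s pre-event baseline window.
The RPE response curve runs one 4 s circuit simulation per (δ, seed);
an increase in agency steepens its positive side (more released cells are
available to burst) and the positive-side slope exceeds the negative-side
magnitude (the dip is floored by silence; aversive-responding cells oppose
it), reproducing the predicted gain/loss asymmetry at the DA level.

## Activation protocols and statistics

The packaged activation experiment runs four conditions — control
(A_control), vSub (A_high), PPTN (sustained 400 Hz NMDA-gated drive at
control agency), both — for n_seeds = 20 wiring/noise seeds each, 12 s per
run with 2 s burn-in, and summarises percent tonically active and mean
active-cell rate. Significance against control uses a two-sided Monte
Carlo permutation test on the mean difference (10 000 shuffles, seeded,
+1-corrected so identical samples give p = 1); Welch's t is available for
speed. The expected pattern, which the acceptance tests check at exactly
these sizes: vSub moves only the population measure, PPTN only the rate
measure, co-application both. The "both" condition is simple
co-application; whether the real manipulations interact is not derivable
from the source account.

## Decision layer

Utility is two-part power, u(x) = g·s·x^0.88 for gains and
−l·λ·s·|x|^0.88 for losses, with s and λ solved from the control anchors
(79 → +50, 48 → −50) and the multipliers (g, l) interpolated linearly in
(multiplier − 1) from (1, 1) at A_control to (1.38, 1.06) at A_high — the
ratios implied by the printed high-agency values 69/50 and 53/50. Agency
below control keeps the control curve. The functional family and exponent
are our choice (canonical prospect-theory curvature); the account itself
constrains only the anchor values and the gain-dominant asymmetry.

Probability weighting defaults to the identity; the shipped alternative is
the Prelec inverse-S w(p) = exp(−(−ln p)^γ), strictly increasing with fixed
endpoints for all γ ∈ (0, 1]. A DA-modulation coefficient can shift γ with
tonic DA, but it defaults to 0 because the direction of that effect is
empirically unresolved.

Discounting is hyperbolic, D(t) = 1/(1 + αt) with t in days and α = 0.01/day
uncoupled. The DA coupling is log α = log α_min + curvature·(DA − DA_opt)²,
with the tonic-DA proxy defined as (fraction active × mean active rate);
control ≈ 2.25 a.u. and DA_opt = 3.0 by default, so moderate agency
increases reduce discounting while pushing an already-high DA level past
the optimum increases it (the overdose logic). Exact ties in delayed choice
go to the sooner option, the impulsive default.

## What the simulations do and do not show

The generator-driven experiments establish that the circuit produces the
qualitative pattern of the in-vivo data under the stated conditions —
directions, dissociations and monotonicities with seeded statistics. They
do not fit quantitative bar heights of the recorded data (axis units of
the concentration figures are arbitrary and are not reproduced), do not
include interneurons, receptor pharmacology, the nigrostriatal system, or
a mechanistic agency-estimation network, and the Poisson drive nodes are a
deliberate simplification of structured afferent activity. Passing tests
therefore support internal consistency of the account, not parameter-level
correspondence with any particular recording.

## Problem sizes

Defaults were chosen so a full property run stays light: populations of
100 per region, 12 s runs (10 s analysed), 20 seeds per condition for
protocol statistics, 4 s runs for RPE events, and 8–20 seeds per point on
response curves. All are configuration fields and scale up without code
changes.
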