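"""Numba inner loop for the disinhibition circuit.

The architecture is fixed by the anatomy: an agency-scaled ventral-subiculum
drive excites the accumbens MSNs, the MSNs inhibit the ventral pallidum, the
pallidum inhibits the VTA dopamine population, and two reward-prediction
drives (PPTN excitatory, RMTN inhibitory) impinge on the dopamine neurons.
Drives are homogeneous Poisson event sources aggregated per target neuron;
synapses are exponential current pulses with integer-step delays.

Everything here takes plain arrays/scalars so it can be jitted; the
user-facing objects live in :mod:`adds.circuit`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_network(
    seed,
    n_steps,
    dt,
    # NAcc (Izhikevich MSN)
    nacc_C, nacc_vr, nacc_vt, nacc_k, nacc_a, nacc_b, nacc_c, nacc_d,
    nacc_vpeak, n_nacc,
    # VP (QIF)
    vp_tau, vp_vr, vp_vc, vp_reset, vp_vpeak, vp_R, vp_bias, vp_noise, n_vp,
    # DA (QIF)
    da_tau, da_vr, da_vc, da_reset, da_vpeak, da_R, da_bias, da_noise, n_da,
    # internal projections (weight matrices already carry the wiring mask)
    W_nacc_vp, tau_nacc_vp, delay_nacc_vp,
    W_vp_da, tau_vp_da, delay_vp_da, da_gaba_reversal, da_nmda_mg,
    # drives: aggregate Poisson event rate (Hz) per target neuron per step
    vsub_rate, w_vsub, tau_vsub,
    pptn_rate, w_pptn, tau_pptn,
    rmtn_rate, w_rmtn, tau_rmtn,
    aversive, aversive_gain,
):
    np.random.seed(seed)

    v1 = np.full(n_nacc, nacc_vr)
    u1 = np.zeros(n_nacc)
    v2 = np.full(n_vp, vp_vr)
    v3 = np.full(n_da, da_vr)

    s_vsub = np.zeros(n_nacc)
    s_nv = np.zeros(n_vp)
    s_vd = np.zeros(n_da)
    s_pptn = np.zeros(n_da)
    s_rmtn = np.zeros(n_da)

    dec_vsub = np.exp(-dt / tau_vsub)
    dec_nv = np.exp(-dt / tau_nacc_vp)
    dec_vd = np.exp(-dt / tau_vp_da)
    dec_pptn = np.exp(-dt / tau_pptn)
    dec_rmtn = np.exp(-dt / tau_rmtn)

    sp1 = np.zeros((n_steps, n_nacc), dtype=np.uint8)
    sp2 = np.zeros((n_steps, n_vp), dtype=np.uint8)
    sp3 = np.zeros((n_steps, n_da), dtype=np.uint8)

    delta_vp = vp_vc - vp_vr
    delta_da = da_vc - da_vr
    ms_to_s = 1e-3

    for t in range(n_steps):
        # --- drive events (aggregate Poisson counts per target) ---
        lam_vsub = vsub_rate[t] * dt * ms_to_s
        if lam_vsub > 0.0:
            for i in range(n_nacc):
                c = np.random.poisson(lam_vsub)
                if c > 0:
                    s_vsub[i] += w_vsub[i] * c
        lam_p = pptn_rate[t] * dt * ms_to_s
        if lam_p > 0.0:
            for i in range(n_da):
                c = np.random.poisson(lam_p)
                if c > 0:
                    s_pptn[i] += w_pptn * c
        lam_r = rmtn_rate[t] * dt * ms_to_s
        if lam_r > 0.0:
            for i in range(n_da):
                c = np.random.poisson(lam_r)
                if c > 0:
                    s_rmtn[i] += w_rmtn * c

        # --- delayed internal spikes ---
        td = t - delay_nacc_vp
        if td >= 0:
            for i in range(n_nacc):
                if sp1[td, i]:
                    for j in range(n_vp):
                        s_nv[j] += W_nacc_vp[j, i]
        td = t - delay_vp_da
        if td >= 0:
            for j in range(n_vp):
                if sp2[td, j]:
                    for k in range(n_da):
                        s_vd[k] += W_vp_da[k, j]

        # --- NAcc MSNs ---
        for i in range(n_nacc):
            I = s_vsub[i]
            v = v1[i]
            u = u1[i]
            dv = (nacc_k * (v - nacc_vr) * (v - nacc_vt) - u + I) / nacc_C
            du = nacc_a * (nacc_b * (v - nacc_vr) - u)
            v += dt * dv
            u += dt * du
            if v >= nacc_vpeak:
                v = nacc_c
                u += nacc_d
                sp1[t, i] = 1
            v1[i] = v
            u1[i] = u

        # --- VP ---
        for j in range(n_vp):
            I = vp_bias - s_nv[j]
            if vp_noise > 0.0:
                I += vp_noise * np.random.randn()
            v = v2[j]
            dv = ((v - vp_vr) * (v - vp_vc) / delta_vp + vp_R * I) / vp_tau
            v += dt * dv
            if v >= vp_vpeak:
                v = vp_reset
                sp2[t, j] = 1
            v2[j] = v

        # --- VTA DA ---
        for k in range(n_da):
            v = v3[k]
            # PPTN input is NMDA-like: Jahr-Stevens Mg block makes it
            # ineffective on hyperpolarized (pallidally silenced) cells
            g_nmda = 1.0 / (1.0 + da_nmda_mg * np.exp(-0.062 * v))
            if aversive[k]:
                I_rpe = g_nmda * s_pptn[k] + aversive_gain * s_rmtn[k]
            else:
                I_rpe = g_nmda * s_pptn[k] - s_rmtn[k]
            I = da_bias[k] + I_rpe
            if da_noise > 0.0:
                I += da_noise * np.random.randn()
            # pallidal inhibition is a GABA conductance (s_vd in nS):
            # divisive near rest, so silenced cells resist excitation
            I -= s_vd[k] * (v - da_gaba_reversal)
            dv = ((v - da_vr) * (v - da_vc) / delta_da + da_R * I) / da_tau
            v += dt * dv
            if v >= da_vpeak:
                v = da_reset
                sp3[t, k] = 1
            v3[k] = v

        # --- synaptic decay ---
        for i in range(n_nacc):
            s_vsub[i] *= dec_vsub
        for j in range(n_vp):
            s_nv[j] *= dec_nv
        for k in range(n_da):
            s_vd[k] *= dec_vd
            s_pptn[k] *= dec_pptn
            s_rmtn[k] *= dec_rmtn

    return sp1, sp2, sp3
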