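"""Fixed-step integration core (numba-compiled).

The membrane equation is advanced with a semi-implicit (backward-Euler on
the ohmic part) update while gating variables use exponential Euler
against their voltage-dependent steady states — the standard staggered
scheme for Hodgkin-Huxley-type stiffness at a fixed dt.  GHK Ca2+
currents are treated explicitly.  A classical RK4 path over the full
state vector is available as an independent reference for step-size
refinement checks.

Synaptic conductances are difference-of-exponentials driven by a
pre-computed event list (grid step, AMPA weight, NMDA weight in nS); the
two exponentials of each component are advanced exactly between events.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._kinetics import gate_tables, ghk_flux, temp_factors

# Parameter-vector layout (see engine.pack_params)
P_GNA, P_GKDR, P_GA, P_GK2, P_GNAP, P_GH, P_GLEAK = range(7)
P_PCAT, P_PCAL = 7, 8
P_ENA, P_EK, P_ELEAK, P_EH = 9, 10, 11, 12
P_CM, P_AREA, P_CAI, P_CAO, P_TEMP, P_VSHIFT = 13, 14, 15, 16, 17, 18
N_PARAMS = 19

STATUS_OK = 0
STATUS_RAILS = 1


@njit(cache=True)
def _ionic_mA(v, gates, p):
    """Total intrinsic current density in mA/cm2 at (v, gates)."""
    i = p[P_GNA] * gates[0] ** 3 * gates[1] * (v - p[P_ENA])
    i += p[P_GKDR] * gates[2] ** 4 * (v - p[P_EK])
    i += ghk_flux(p[P_PCAT] * gates[3] ** 2 * gates[4], v,
                  p[P_CAI], p[P_CAO], p[P_TEMP])
    i += ghk_flux(p[P_PCAL] * gates[5] ** 2, v,
                  p[P_CAI], p[P_CAO], p[P_TEMP])
    i += p[P_GA] * gates[6] ** 4 * gates[7] * (v - p[P_EK])
    i += p[P_GK2] * gates[8] * gates[9] * (v - p[P_EK])
    i += p[P_GNAP] * gates[10] * (v - p[P_ENA])
    i += p[P_GH] * gates[11] * (v - p[P_EH])
    i += p[P_GLEAK] * (v - p[P_ELEAK])
    return i


@njit(cache=True)
def _deriv(v, gates, p, tf, g_syn_mS, i_inj_uA):
    """Right-hand side for the RK4 reference path.

    ``g_syn_mS``: synaptic conductance density (mS/cm2, Mg block already
    applied); ``i_inj_uA``: injected current density (uA/cm2).
    """
    dv_gates = np.empty(12)
    inf, tau = gate_tables(v, p[P_VSHIFT], tf)
    for k in range(12):
        dv_gates[k] = (inf[k] - gates[k]) / tau[k]
    i_total = _ionic_mA(v, gates, p) * 1e3  # -> uA/cm2
    i_total += g_syn_mS * v  # E_syn = 0
    dv = (-i_total + i_inj_uA) / p[P_CM]
    return dv, dv_gates


@njit(cache=True)
def run_trial(v0, gates0, p, dt, n_steps,
              evt_step, evt_stream, evt_wa, evt_wn,
              nmda_caps,
              ampa_rise, ampa_decay, nmda_rise, nmda_decay,
              ampa_norm, nmda_norm, mg_mM,
              i_bias_nA, pulse_amp_nA, pulse_start, pulse_end,
              method):
    """Integrate ``n_steps`` steps of size ``dt`` from (v0, gates0).

    ``evt_step`` must be sorted ascending (grid indices); ``evt_wa`` /
    ``evt_wn`` are per-event peak conductance weights in nS and
    ``evt_stream`` the afferent stream each event belongs to.  The NMDA
    conductance of stream ``s`` is clipped at ``nmda_caps[s]`` (receptor
    saturation); AMPA sums linearly.  ``method`` 0 = semi-implicit
    exponential Euler, 1 = RK4 reference.

    Returns ``(v_trace, gates, status, n_done)``; the trace has
    ``n_steps + 1`` samples and is NaN beyond ``n_done`` if the voltage
    left the (-150, 80) mV sanity rails.
    """
    tf = temp_factors(p[P_TEMP])
    inv_area = 1.0 / p[P_AREA]
    v = v0
    gates = gates0.copy()
    v_out = np.full(n_steps + 1, np.nan)
    v_out[0] = v

    # synaptic exponential states (nS); g = norm * (d - r)
    n_streams = nmda_caps.shape[0]
    sa_r = 0.0
    sa_d = 0.0
    sn_r = np.zeros(n_streams)
    sn_d = np.zeros(n_streams)
    dec_ar = math.exp(-dt / ampa_rise)
    dec_ad = math.exp(-dt / ampa_decay)
    dec_nr = math.exp(-dt / nmda_rise)
    dec_nd = math.exp(-dt / nmda_decay)

    n_evt = evt_step.shape[0]
    ptr = 0
    status = STATUS_OK
    n_done = n_steps

    for step in range(n_steps):
        # decay synaptic states across this step, then deposit events
        sa_r *= dec_ar
        sa_d *= dec_ad
        for s in range(n_streams):
            sn_r[s] *= dec_nr
            sn_d[s] *= dec_nd
        while ptr < n_evt and evt_step[ptr] == step:
            sa_r += evt_wa[ptr]
            sa_d += evt_wa[ptr]
            s = evt_stream[ptr]
            sn_r[s] += evt_wn[ptr]
            sn_d[s] += evt_wn[ptr]
            ptr += 1

        g_ampa_nS = ampa_norm * (sa_d - sa_r)
        g_nmda_nS = 0.0
        for s in range(n_streams):
            g_lin = nmda_norm * (sn_d[s] - sn_r[s])
            g_nmda_nS += min(g_lin, nmda_caps[s])
        mg = 1.0 / (1.0 + mg_mM * math.exp(-0.062 * v) / 3.57)
        g_syn_mS = (g_ampa_nS + g_nmda_nS * mg) * 1e-6 * inv_area

        i_inj = i_bias_nA
        if pulse_start <= step < pulse_end:
            i_inj += pulse_amp_nA
        i_inj_uA = i_inj * 1e-3 * inv_area  # nA -> uA/cm2

        if method == 0:
            inf, tau = gate_tables(v, p[P_VSHIFT], tf)
            for k in range(12):
                gates[k] = inf[k] + (gates[k] - inf[k]) * math.exp(-dt / tau[k])
            # ohmic part implicit, GHK explicit
            g_sum = (p[P_GNA] * gates[0] ** 3 * gates[1]
                     + p[P_GKDR] * gates[2] ** 4
                     + p[P_GA] * gates[6] ** 4 * gates[7]
                     + p[P_GK2] * gates[8] * gates[9]
                     + p[P_GNAP] * gates[10]
                     + p[P_GH] * gates[11]
                     + p[P_GLEAK]) * 1e3  # S/cm2 -> mS/cm2
            e_sum = (p[P_GNA] * gates[0] ** 3 * gates[1] * p[P_ENA]
                     + p[P_GKDR] * gates[2] ** 4 * p[P_EK]
                     + p[P_GA] * gates[6] ** 4 * gates[7] * p[P_EK]
                     + p[P_GK2] * gates[8] * gates[9] * p[P_EK]
                     + p[P_GNAP] * gates[10] * p[P_ENA]
                     + p[P_GH] * gates[11] * p[P_EH]
                     + p[P_GLEAK] * p[P_ELEAK]) * 1e3
            g_sum += g_syn_mS  # E_syn = 0 adds nothing to e_sum
            i_ghk = (ghk_flux(p[P_PCAT] * gates[3] ** 2 * gates[4], v,
                              p[P_CAI], p[P_CAO], p[P_TEMP])
                     + ghk_flux(p[P_PCAL] * gates[5] ** 2, v,
                                p[P_CAI], p[P_CAO], p[P_TEMP])) * 1e3
            rhs = v + (dt / p[P_CM]) * (e_sum - i_ghk + i_inj_uA)
            v = rhs / (1.0 + (dt / p[P_CM]) * g_sum)
        else:
            dv1, dg1 = _deriv(v, gates, p, tf, g_syn_mS, i_inj_uA)
            dv2, dg2 = _deriv(v + 0.5 * dt * dv1, gates + 0.5 * dt * dg1,
                              p, tf, g_syn_mS, i_inj_uA)
            dv3, dg3 = _deriv(v + 0.5 * dt * dv2, gates + 0.5 * dt * dg2,
                              p, tf, g_syn_mS, i_inj_uA)
            dv4, dg4 = _deriv(v + dt * dv3, gates + dt * dg3,
                              p, tf, g_syn_mS, i_inj_uA)
            v = v + (dt / 6.0) * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
            for k in range(12):
                gates[k] += (dt / 6.0) * (dg1[k] + 2.0 * dg2[k]
                                          + 2.0 * dg3[k] + dg4[k])
                if gates[k] < 0.0:
                    gates[k] = 0.0
                elif gates[k] > 1.0:
                    gates[k] = 1.0

        v_out[step + 1] = v
        if not (-150.0 < v < 80.0) or not math.isfinite(v):
            status = STATUS_RAILS
            n_done = step + 1
            break

    return v_out, gates, status, n_done
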