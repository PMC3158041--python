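"""Compiled inner loop of the compartmental Hodgkin–Huxley integrator.

Voltage is advanced with an implicit theta-method (theta = 1: backward
Euler, theta = 0.5: Crank–Nicolson) over the tridiagonal cable system;
gating variables use the exponential-relaxation (Rush–Larsen) update with
steady states and per-step relaxation factors pre-tabulated on a uniform
voltage grid, which removes all transcendental calls from the hot loop.
Internal calcium follows its exact first-order update with the calcium
current frozen over the step.

All state arrays are modified in place; the caller owns allocation.
Units: mV, ms, nA, µS, nF, mM.
"""

import numpy as np
from numba import njit

#: sentinel returned in place of the failing step index on success
OK = -1


@njit(cache=True, fastmath=True)
def integrate(
    v,            # (n_comp,) voltage state, modified in place
    x,            # (n_gates,) gating state
    ca_state,     # (1,) internal calcium, mM
    i_inj,        # (n_steps,) injected current at the soma, nA
    dt,
    theta,
    cm_dt,        # (n_comp,) capacitance / dt, nF/ms
    g_leak,       # (n_comp,) leak conductance, µS
    e_leak,
    g_ax,         # (n_comp-1,) axial conductances, µS
    gbar,         # (n_chan,) absolute maximal conductances at the soma, µS
    erev,         # (n_chan,)
    gate_chan,    # (n_gates,) channel index of each gate
    gate_power,   # (n_gates,)
    gate_is_ca,   # (n_gates,) 1 for the calcium-sensed gate
    tab_inf,      # (n_gates, n_v) steady-state tables
    tab_relax,    # (n_gates, n_v) exp(-dt/tau) tables
    v_min,
    dv_inv,
    n_v,
    sk_ec50,
    sk_hill,
    sk_relax,     # exp(-dt/tau_z) for the calcium gate
    ca_chan,      # index of the calcium-carrying channel, or -1
    ca_rest,
    ca_tau,
    ca_kin,       # influx coefficient, mM/(ms*nA)
    out_v,        # (n_steps+1,) recorded somatic voltage
    out_ca,       # (n_steps+1,)
):
    n_comp = v.shape[0]
    n_chan = gbar.shape[0]
    n_gates = x.shape[0]
    n_steps = i_inj.shape[0]

    g_chan = np.empty(n_chan)
    lo = np.empty(n_comp)
    di = np.empty(n_comp)
    up = np.empty(n_comp)
    rhs = np.empty(n_comp)
    cp = np.empty(n_comp)
    dp = np.empty(n_comp)

    out_v[0] = v[0]
    out_ca[0] = ca_state[0]

    for step in range(n_steps):
        vs = v[0]

        # --- gating update (Rush-Larsen, tabulated) ---------------------
        pos = (vs - v_min) * dv_inv
        if pos < 0.0:
            pos = 0.0
        elif pos > n_v - 1.001:
            pos = n_v - 1.001
        k0 = int(pos)
        frac = pos - k0
        ca = ca_state[0]
        for g in range(n_gates):
            if gate_is_ca[g] == 1:
                xinf = 1.0 / (1.0 + (sk_ec50 / ca) ** sk_hill)
                x[g] = xinf + (x[g] - xinf) * sk_relax
            else:
                xinf = tab_inf[g, k0] + frac * (tab_inf[g, k0 + 1] - tab_inf[g, k0])
                rel = tab_relax[g, k0] + frac * (tab_relax[g, k0 + 1] - tab_relax[g, k0])
                x[g] = xinf + (x[g] - xinf) * rel

        # --- channel conductances --------------------------------------
        for c in range(n_chan):
            g_chan[c] = gbar[c]
        for g in range(n_gates):
            xv = x[g]
            p = gate_power[g]
            acc = xv
            for _ in range(p - 1):
                acc *= xv
            g_chan[gate_chan[g]] *= acc

        # --- calcium pool (exact 1st-order, frozen I_Ca) ----------------
        if ca_chan >= 0:
            i_ca = g_chan[ca_chan] * (vs - erev[ca_chan])
            ca_ss = ca_rest - ca_kin * i_ca * ca_tau
            if ca_ss < 1e-12:
                ca_ss = 1e-12
            efac = np.exp(-dt / ca_tau)
            ca_state[0] = ca_ss + (ca - ca_ss) * efac

        # --- voltage step: theta-method on the cable --------------------
        g_active = 0.0
        ge_active = 0.0
        for c in range(n_chan):
            g_active += g_chan[c]
            ge_active += g_chan[c] * erev[c]

        for i in range(n_comp):
            gi = g_leak[i]
            gei = g_leak[i] * e_leak
            inj = 0.0
            if i == 0:
                gi += g_active
                gei += ge_active
                inj = i_inj[step]
            gax_sum = 0.0
            off_lo = 0.0
            off_up = 0.0
            expl = 0.0
            if i > 0:
                gax_sum += g_ax[i - 1]
                off_lo = -theta * g_ax[i - 1]
                expl += g_ax[i - 1] * (v[i - 1] - v[i])
            if i < n_comp - 1:
                gax_sum += g_ax[i]
                off_up = -theta * g_ax[i]
                expl += g_ax[i] * (v[i + 1] - v[i])
            di[i] = cm_dt[i] + theta * (gi + gax_sum)
            lo[i] = off_lo
            up[i] = off_up
            # explicit part: (1-theta) * total ionic+axial current at V_old
            expl += gei - gi * v[i]
            rhs[i] = cm_dt[i] * v[i] + theta * (gei + inj) + (1.0 - theta) * (expl + inj)

        # Thomas algorithm
        cp[0] = up[0] / di[0]
        dp[0] = rhs[0] / di[0]
        for i in range(1, n_comp):
            m = di[i] - lo[i] * cp[i - 1]
            cp[i] = up[i] / m
            dp[i] = (rhs[i] - lo[i] * dp[i - 1]) / m
        v[n_comp - 1] = dp[n_comp - 1]
        for i in range(n_comp - 2, -1, -1):
            v[i] = dp[i] - cp[i] * v[i + 1]

        if not np.isfinite(v[0]):
            return step
        out_v[step + 1] = v[0]
        out_ca[step + 1] = ca_state[0]

    return OK
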