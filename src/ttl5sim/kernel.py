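"""Integration kernel: staggered implicit stepping on a compartment tree.

Per step: (1) every gate relaxes exactly exponentially toward its steady
state at the current voltage, (2) calcium pools advance analytically under
the instantaneous Ca2+ current, (3) the voltage is advanced by one backward
Euler step, solving the (symmetric, tree-structured) linear system exactly
in O(n) with Hines elimination (compartments are ordered parents-first).

The module is plain NumPy + math and is JIT-compiled when numba is
available (see ttl5sim._compat).
"""

import math

import numpy as np

from ._compat import maybe_njit
from .channels import NAT, CAHVA, CALVA, KSLOW, _gate_rates

_BIG = 1e12  # penalty weight pinning a clamped compartment to its command


@maybe_njit
def _n_gates(type_id):
    if type_id == NAT or type_id == CAHVA or type_id == CALVA:
        return 2
    return 1


@maybe_njit
def _open_fraction(type_id, g0, g1):
    if type_id == NAT:
        return g0 * g0 * g0 * g1
    if type_id == CAHVA or type_id == CALVA:
        return g0 * g0 * g1
    if type_id == KSLOW:
        return g0 * g0
    return g0


@maybe_njit
def init_gates(ch_type, ch_off, ch_comp, ch_params, v, ca):
    """Gate state matrix [m_instances_x_comps, 2] at equilibrium for (v, ca)."""
    m = ch_comp.shape[0]
    gstate = np.zeros((m, 2))
    for k in range(ch_type.shape[0]):
        t = ch_type[k]
        p = ch_params[k]
        for j in range(ch_off[k], ch_off[k + 1]):
            i = ch_comp[j]
            for g in range(_n_gates(t)):
                inf, _ = _gate_rates(t, g, v[i], p, ca[i])
                gstate[j, g] = inf
    return gstate


@maybe_njit
def integrate(
    nsteps, dt, v, parent, gax, cm, gpas, epas,
    ch_type, ch_off, ch_comp, ch_gbar, ch_gdens, ch_erev, ch_params, gstate,
    has_pool, ca, ca_tau, ca_phi, ca_rest, ca_out,
    stim_comp, stim_wave, clamp_comp, clamp_wave,
    rec_comp, out, i_clamp, v_limit,
):
    n = v.shape[0]
    nch = ch_type.shape[0]

    cm_dt = cm / dt
    gax_diag = np.zeros(n)
    for i in range(n):
        if parent[i] >= 0:
            gax_diag[i] += gax[i]
            gax_diag[parent[i]] += gax[i]

    gsum = np.zeros(n)
    gesum = np.zeros(n)
    ica = np.zeros(n)
    d = np.zeros(n)
    rhs = np.zeros(n)

    for r in range(rec_comp.shape[0]):
        out[r, 0] = v[rec_comp[r]]
    i_clamp[0] = 0.0

    for step in range(nsteps):
        for i in range(n):
            gsum[i] = 0.0
            gesum[i] = 0.0
            ica[i] = 0.0

        # gates + channel conductances
        for k in range(nch):
            t = ch_type[k]
            e = ch_erev[k]
            p = ch_params[k]
            ng = _n_gates(t)
            for j in range(ch_off[k], ch_off[k + 1]):
                i = ch_comp[j]
                vi = v[i]
                ci = ca[i]
                for g in range(ng):
                    inf, tau = _gate_rates(t, g, vi, p, ci)
                    gstate[j, g] = inf + (gstate[j, g] - inf) * math.exp(-dt / tau)
                op = _open_fraction(t, gstate[j, 0], gstate[j, 1])
                gc = ch_gbar[j] * op
                ech = e
                if t == CAHVA or t == CALVA:
                    # Nernst reversal from the local pool, if one exists
                    if ca_out[i] > 0.0:
                        cin = ci if ci > 1e-6 else 1e-6
                        ech = 13.27 * math.log(ca_out[i] / cin)
                    ica[i] += ch_gdens[j] * op * (vi - ech) * 1e-3  # mA/cm²
                gsum[i] += gc
                gesum[i] += gc * ech

        # calcium pools (exact exponential update at fixed I_Ca)
        for i in range(n):
            if has_pool[i]:
                target = ca_rest[i] - ca_phi[i] * ca_tau[i] * ica[i]
                c = target + (ca[i] - target) * math.exp(-dt / ca_tau[i])
                ca[i] = c if c > 0.0 else 0.0

        # assemble backward Euler system
        for i in range(n):
            d[i] = cm_dt[i] + gpas[i] + gsum[i] + gax_diag[i]
            rhs[i] = cm_dt[i] * v[i] + gpas[i] * epas[i] + gesum[i]
        for s in range(stim_comp.shape[0]):
            rhs[stim_comp[s]] += stim_wave[s, step]
        if clamp_comp >= 0:
            d[clamp_comp] += _BIG
            rhs[clamp_comp] += _BIG * clamp_wave[step]

        v_old_clamp = v[clamp_comp] if clamp_comp >= 0 else 0.0

        # Hines elimination (parents-first ordering)
        for i in range(n - 1, 0, -1):
            pidx = parent[i]
            f = gax[i] / d[i]
            d[pidx] -= f * gax[i]
            rhs[pidx] += f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] + gax[i] * v[parent[i]]) / d[i]

        # divergence guard
        for i in range(n):
            if not (-v_limit < v[i] < v_limit):
                return 1, step + 1

        if clamp_comp >= 0:
            c = clamp_comp
            inet = (
                cm_dt[c] * (v[c] - v_old_clamp)
                + (gpas[c] + gsum[c]) * v[c]
                - (gpas[c] * epas[c] + gesum[c])
            )
            if parent[c] >= 0:
                inet += gax[c] * (v[c] - v[parent[c]])
            for i in range(n):
                if parent[i] == c:
                    inet += gax[i] * (v[c] - v[i])
            for s in range(stim_comp.shape[0]):
                if stim_comp[s] == c:
                    inet -= stim_wave[s, step]
            i_clamp[step + 1] = inet

        for r in range(rec_comp.shape[0]):
            out[r, step + 1] = v[rec_comp[r]]

    return 0, nsteps
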