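"""Numba inner loop for the propagating-action-potential cable solver.

The cable PDE is advanced with the staggered scheme of Hines: gating
variables are updated on half steps with an exponential integrator using
rates frozen at the current voltage, then the voltage is advanced with a
backward-Euler step that is linear in V (ionic conductances evaluated at the
half-step gates), solved as a tridiagonal system by the Thomas algorithm.

The exponential gate update ``x <- x e + x_inf (1 - e)`` with
``e = exp(-dt (alpha + beta))`` uses per-voltage tables of ``e`` and
``x_inf (1 - e)`` precomputed from the analytic rate expressions in
:mod:`chanevo.cable`; the table spacing (0.025 mV) keeps the linear
interpolation error orders of magnitude below the discretization error of
the scheme.
"""

import numba
import numpy as np

__all__ = ["run_cable"]


@numba.njit(cache=True, fastmath=True)
def run_cable(
    v,
    n,
    m,
    h,
    n_steps,
    dt,
    dx,
    g_axial,
    c0,
    cg_scale,
    g_na,
    g_k,
    g_l,
    e_na,
    e_k,
    v_l,
    tables,
    v_table_min,
    inv_dv,
    stim_density,
    stim_steps,
    stim_nodes,
    rec_idx,
    mid_idx,
    expand_cm,
):
    """Advance the cable ``n_steps`` and record voltage/sodium-current traces.

    Arrays ``v, n, m, h`` are modified in place (final state).  Returns
    ``(v_rec, i_na_rec, status)`` where ``status`` is -1 on success or the
    step index at which the voltage became non-finite.
    """
    nx = v.shape[0]
    n_rec = rec_idx.shape[0]
    n_pts = tables.shape[1]

    v_rec = np.empty((n_steps + 1, n_rec))
    i_na_rec = np.empty(n_steps + 1)
    for j in range(n_rec):
        v_rec[0, j] = v[rec_idx[j]]
    i_na_rec[0] = g_na * m[mid_idx] ** 3 * h[mid_idx] * (v[mid_idx] - e_na)

    k_ax = g_axial / (dx * dx)
    inv_dt = 1.0 / dt

    diag = np.empty(nx)
    rhs = np.empty(nx)
    cp = np.empty(nx)  # Thomas scratch
    cm_prev = c0 + cg_scale * (1.0 - m)

    for step in range(n_steps):
        # --- gate update (exponential integrator, rates at V(t)) ---
        for i in range(nx):
            pos = (v[i] - v_table_min) * inv_dv
            if pos < 0.0:
                pos = 0.0
            elif pos > n_pts - 1.001:
                pos = n_pts - 1.001
            i0 = int(pos)
            w = pos - i0
            cn = tables[0, i0] + w * (tables[0, i0 + 1] - tables[0, i0])
            en = tables[1, i0] + w * (tables[1, i0 + 1] - tables[1, i0])
            cm_ = tables[2, i0] + w * (tables[2, i0 + 1] - tables[2, i0])
            em = tables[3, i0] + w * (tables[3, i0 + 1] - tables[3, i0])
            ch = tables[4, i0] + w * (tables[4, i0 + 1] - tables[4, i0])
            eh = tables[5, i0] + w * (tables[5, i0 + 1] - tables[5, i0])

            n[i] = n[i] * en + cn
            m[i] = m[i] * em + cm_
            h[i] = h[i] * eh + ch

        # --- assemble implicit voltage system ---
        for i in range(nx):
            g_na_open = g_na * m[i] ** 3 * h[i]
            g_k_open = g_k * n[i] ** 4
            cm = c0 + cg_scale * (1.0 - m[i])
            a_dt = cm * inv_dt
            g_sum = g_na_open + g_k_open + g_l
            diag[i] = a_dt + g_sum + 2.0 * k_ax
            if expand_cm:
                # d(Cm V)/dt expansion: V dCm/dt term, Cm from the gate step
                diag[i] += (cm - cm_prev[i]) * inv_dt
            rhs[i] = a_dt * v[i] + g_na_open * e_na + g_k_open * e_k + g_l * v_l
            cm_prev[i] = cm
        # sealed ends: one axial neighbour only
        diag[0] -= k_ax
        diag[nx - 1] -= k_ax
        if step < stim_steps:
            for i in range(stim_nodes):
                rhs[i] += stim_density

        # --- Thomas algorithm (constant off-diagonal -k_ax) ---
        cp[0] = -k_ax / diag[0]
        rhs[0] = rhs[0] / diag[0]
        for i in range(1, nx):
            denom = diag[i] + k_ax * cp[i - 1]
            cp[i] = -k_ax / denom
            rhs[i] = (rhs[i] + k_ax * rhs[i - 1]) / denom
        v[nx - 1] = rhs[nx - 1]
        for i in range(nx - 2, -1, -1):
            v[i] = rhs[i] - cp[i] * v[i + 1]

        if not np.isfinite(v[0]) or not np.isfinite(v[nx - 1]):
            return v_rec, i_na_rec, step

        for j in range(n_rec):
            v_rec[step + 1, j] = v[rec_idx[j]]
        i_na_rec[step + 1] = g_na * m[mid_idx] ** 3 * h[mid_idx] * (v[mid_idx] - e_na)

    return v_rec, i_na_rec, -1
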