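"""Compiled inner loop of the ventilation engine.

The time march is an implicit first-order scheme on the coupled
pressure/recruitment system: over a step ``dt`` the trial recruited fractions
are ``s_i(P) = min(1, s_i + dt * max(0, kU_i (P - Pc_i)) / L_i)`` and the new
pressure is the root of the volume-conservation residual

    R(P) = V_finger(P, s(P)) + V_prox(P) + V_acini(P) - V_ref - Q * t_new

which is continuous and strictly increasing in ``P`` (every term is), so a
bracketed Illinois iteration is unconditionally convergent.  Solving the
advance implicitly lets the pressure "ride" the frontier yield pressures
during avalanches without the stall/peel chatter an explicit scheme produces.
Steps on which an airway would cross ``s = 1`` are re-solved at the earliest
crossing time so completion (and child-unlocking) times are resolved sharply.

State codes: 0 blocked (parent not recruited), 1 unlocked (stalled or
peeling depending on the current pressure), 2 recruited.
"""

import numpy as np
from numba import njit

TERM_OK = 0
TERM_MAX_STEPS = 2
TERM_SOLVER = 3

_COMPLETE_TOL = 1e-9


@njit(cache=True)
def _alpha(P, a0, n1, n2, P1, P2):
    if P <= 0.0:
        return a0 * (1.0 - P / P1) ** (-n1)
    return 1.0 - (1.0 - a0) * (1.0 - P / P2) ** (-n2)


@njit(cache=True)
def _residual(
    P, dt, t_new, s, state,
    aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc, aw_kU,
    px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
    ac_PA, ac_K, ac_VA,
    Q, V_ref,
):
    V = 0.0
    n = aw_L.shape[0]
    for i in range(n):
        st = state[i]
        if st == 0:
            continue
        if st == 2:
            se = 1.0
        else:
            u = aw_kU[i] * (P - aw_Pc[i])
            se = s[i]
            if u > 0.0:
                se = se + dt * u / aw_L[i]
                if se > 1.0:
                    se = 1.0
        if se > 0.0:
            V += se * aw_L[i] * aw_Amax[i] * _alpha(
                P, aw_alpha0[i], aw_n1[i], aw_n2[i], aw_P1[i], aw_P2[i]
            )
    for j in range(px_wl.shape[0]):
        V += px_wl[j] * px_Amax[j] * _alpha(
            P, px_alpha0[j], px_n1[j], px_n2[j], px_P1[j], px_P2[j]
        )
    if P > ac_PA:
        vac = ac_VA * (1.0 - np.exp(-ac_K * (P - ac_PA)))
        for k in range(32):
            if state[31 + k] == 2:
                V += vac
    return V - V_ref - Q * t_new


@njit(cache=True)
def _solve(
    P_guess, dt, t_new, s, state,
    aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc, aw_kU,
    px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
    ac_PA, ac_K, ac_VA,
    Q, V_ref, vol_tol,
):
    f0 = _residual(
        P_guess, dt, t_new, s, state,
        aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc, aw_kU,
        px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
        ac_PA, ac_K, ac_VA, Q, V_ref,
    )
    if abs(f0) <= vol_tol:
        return P_guess
    # bracket the root; a carries R < 0 (low side), b carries R > 0
    step = 50.0  # dyn cm^-2
    if f0 > 0.0:
        b = P_guess
        fb = f0
        a = b - step
        fa = _residual(
            a, dt, t_new, s, state,
            aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc, aw_kU,
            px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
            ac_PA, ac_K, ac_VA, Q, V_ref,
        )
        it = 0
        while fa > 0.0 and it < 120:
            b = a
            fb = fa
            step *= 2.0
            a -= step
            fa = _residual(
                a, dt, t_new, s, state,
                aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc,
                aw_kU,
                px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
                ac_PA, ac_K, ac_VA, Q, V_ref,
            )
            it += 1
        if fa > 0.0:
            return np.nan
    else:
        a = P_guess
        fa = f0
        b = a + step
        fb = _residual(
            b, dt, t_new, s, state,
            aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc, aw_kU,
            px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
            ac_PA, ac_K, ac_VA, Q, V_ref,
        )
        it = 0
        while fb < 0.0 and it < 120:
            a = b
            fa = fb
            step *= 2.0
            b += step
            fb = _residual(
                b, dt, t_new, s, state,
                aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc,
                aw_kU,
                px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
                ac_PA, ac_K, ac_VA, Q, V_ref,
            )
            it += 1
        if fb < 0.0:
            return np.nan
    # Illinois regula falsi on the maintained bracket
    side = 0
    for _ in range(400):
        x = (a * fb - b * fa) / (fb - fa)
        if not (a < x < b):
            x = 0.5 * (a + b)
        fx = _residual(
            x, dt, t_new, s, state,
            aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc, aw_kU,
            px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
            ac_PA, ac_K, ac_VA, Q, V_ref,
        )
        if abs(fx) <= vol_tol or (b - a) < 1e-12 * (1.0 + abs(x)):
            return x
        if fx < 0.0:
            a = x
            fa = fx
            if side == -1:
                fb *= 0.5
            side = -1
        else:
            b = x
            fb = fx
            if side == 1:
                fa *= 0.5
            side = 1
    return 0.5 * (a + b)


@njit(cache=True)
def run_kernel(
    aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc, aw_kU,
    aw_Goff, aw_Gden,
    px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
    ac_PA, ac_K, ac_VA,
    Q, T_Q, P_init,
    ds_cap, dp_cap, dt_max, dt_init, dt_floor, vol_tol, max_steps,
):
    n = aw_L.shape[0]
    s = np.zeros(n)
    state = np.zeros(n, dtype=np.int8)
    state[0] = 1
    t_start = np.full(n, -1.0)
    t_complete = np.full(n, -1.0)
    g_max = np.zeros(n)
    ac_time = np.full(32, -1.0)

    V_ref = _residual(
        P_init, 0.0, 0.0, s, state,
        aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc, aw_kU,
        px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
        ac_PA, ac_K, ac_VA, 0.0, 0.0,
    )

    tr_t = np.empty(max_steps)
    tr_P = np.empty(max_steps)
    tr_nrec = np.empty(max_steps, dtype=np.int32)
    tr_nac = np.empty(max_steps, dtype=np.int32)
    tr_npeel = np.empty(max_steps, dtype=np.int32)
    tr_resid = np.empty(max_steps)
    tr_t[0] = 0.0
    tr_P[0] = P_init
    tr_nrec[0] = 0
    tr_nac[0] = 0
    tr_npeel[0] = 0
    tr_resid[0] = 0.0

    t = 0.0
    P = P_init
    dt = dt_init
    nrec = 0
    nac = 0
    istep = 0
    term = TERM_OK

    while t < T_Q - 1e-15:
        if istep >= max_steps - 1:
            term = TERM_MAX_STEPS
            break
        dt_eff = dt
        if t + dt_eff > T_Q:
            dt_eff = T_Q - t
        t_new = t + dt_eff
        P_new = _solve(
            P, dt_eff, t_new, s, state,
            aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc, aw_kU,
            px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
            ac_PA, ac_K, ac_VA, Q, V_ref, vol_tol,
        )
        if np.isnan(P_new):
            term = TERM_SOLVER
            break
        # sub-step to the earliest s = 1 crossing so completions are sharp
        dt_cross = dt_eff
        for i in range(n):
            if state[i] == 1 and s[i] < 1.0:
                u = aw_kU[i] * (P_new - aw_Pc[i])
                if u > 0.0 and s[i] + dt_eff * u / aw_L[i] >= 1.0:
                    dti = (1.0 - s[i]) * aw_L[i] / u
                    if dti < dt_cross:
                        dt_cross = dti
        if dt_cross < dt_eff * (1.0 - 1e-12):
            dt_eff = max(dt_cross, 1e-12)
            t_new = t + dt_eff
            P_new = _solve(
                P, dt_eff, t_new, s, state,
                aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc,
                aw_kU,
                px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
                ac_PA, ac_K, ac_VA, Q, V_ref, vol_tol,
            )
            if np.isnan(P_new):
                term = TERM_SOLVER
                break
        # commit the advance; record tip stresses while peeling
        npeel = 0
        for i in range(n):
            if state[i] == 1:
                u = aw_kU[i] * (P_new - aw_Pc[i])
                if u > 0.0:
                    se = s[i] + dt_eff * u / aw_L[i]
                    if se > 1.0:
                        se = 1.0
                    if se > s[i]:
                        npeel += 1
                        if t_start[i] < 0.0:
                            t_start[i] = t
                        g = (P_new - aw_Goff[i]) / aw_Gden[i]
                        if g > g_max[i]:
                            g_max[i] = g
                        s[i] = se
        for i in range(n):
            if state[i] == 1 and s[i] >= 1.0 - _COMPLETE_TOL:
                s[i] = 1.0
                state[i] = 2
                t_complete[i] = t_new
                nrec += 1
                if i < 31:
                    state[2 * i + 1] = 1
                    state[2 * i + 2] = 1
        new_open = False
        if P_new >= ac_PA:
            for k in range(32):
                if ac_time[k] < 0.0 and state[31 + k] == 2:
                    ac_time[k] = t_new
                    nac += 1
                    new_open = True
        if new_open:
            # an acinus switched on while P > P_A (its parent completed this
            # step): redistribute the delivered volume into the new
            # compartment by re-solving the pressure at fixed s and t.
            P_re = _solve(
                P_new, 0.0, t_new, s, state,
                aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc,
                aw_kU,
                px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
                ac_PA, ac_K, ac_VA, Q, V_ref, vol_tol,
            )
            if np.isnan(P_re):
                term = TERM_SOLVER
                break
            P_new = P_re
        resid = _residual(
            P_new, 0.0, t_new, s, state,
            aw_alpha0, aw_n1, aw_n2, aw_P1, aw_P2, aw_Amax, aw_L, aw_Pc, aw_kU,
            px_alpha0, px_n1, px_n2, px_P1, px_P2, px_Amax, px_wl,
            ac_PA, ac_K, ac_VA, Q, V_ref,
        )
        istep += 1
        tr_t[istep] = t_new
        tr_P[istep] = P_new
        tr_nrec[istep] = nrec
        tr_nac[istep] = nac
        tr_npeel[istep] = npeel
        tr_resid[istep] = abs(resid)
        # adaptive step: limit recruited-fraction advance and pressure change
        dP = abs(P_new - P)
        dt_next = dt_eff * 2.0
        for i in range(n):
            if state[i] == 1 and s[i] < 1.0:
                u = aw_kU[i] * (P_new - aw_Pc[i])
                if u > 0.0:
                    lim = ds_cap * aw_L[i] / u
                    if lim < dt_next:
                        dt_next = lim
        if dP > 1e-30:
            lim = dt_eff * dp_cap / dP
            if lim < dt_next:
                dt_next = lim
        if dt_next > dt_max:
            dt_next = dt_max
        if dt_next < dt_floor:
            dt_next = dt_floor
        dt = dt_next
        P = P_new
        t = t_new

    n_rows = istep + 1
    return (
        tr_t[:n_rows], tr_P[:n_rows], tr_nrec[:n_rows], tr_nac[:n_rows],
        tr_npeel[:n_rows], tr_resid[:n_rows],
        s, state, t_start, t_complete, g_max, ac_time, V_ref, term,
    )
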