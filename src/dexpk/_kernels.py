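"""Compiled numerical kernels for the mixed-effects objective.

The per-subject Laplace contribution (three-compartment kinetics, penalised
Gauss-Newton search for the conditional mode, Gauss-Newton curvature) runs in
nopython mode; the population objective is a single compiled call over flat,
offset-indexed subject arrays. The interpreted kinetics in ``model_core`` is
the reference these kernels are tested against.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_2PI = np.log(2.0 * np.pi)


@njit(cache=True, error_model="numpy")
def _conc_profile(p, knots, rates, bolus_t, bolus_a, times, out):
    """Central concentrations for one parameter set.

    p = (cl, v1, v2, v3, q2, q3); piecewise-constant input defined by
    ``knots``/``rates`` with instantaneous central additions ``bolus_*``.
    ``times`` must be sorted ascending. Writes into ``out``.
    """
    cl, v1, v2, v3, q2, q3 = p[0], p[1], p[2], p[3], p[4], p[5]
    k10 = cl / v1
    a = np.zeros((3, 3))
    a[0, 0] = -(k10 + q2 / v1 + q3 / v1)
    a[0, 1] = q2 / v2
    a[0, 2] = q3 / v3
    a[1, 0] = q2 / v1
    a[1, 1] = -q2 / v2
    a[2, 0] = q3 / v1
    a[2, 2] = -q3 / v3
    wc, vc = np.linalg.eig(a)
    lam = wc.real.copy()
    vec = vc.real.copy()
    vinv = np.linalg.inv(vec)

    n = times.shape[0]
    nseg = knots.shape[0]
    state = np.zeros(3)
    ti = 0
    for seg in range(nseg):
        t0 = knots[seg]
        for b in range(bolus_t.shape[0]):
            if bolus_t[b] == t0:
                state[0] += bolus_a[b]
        rate = rates[seg]
        t1 = knots[seg + 1] if seg + 1 < nseg else np.inf
        # z-space initial condition for this segment
        z0 = vinv @ state
        while ti < n and times[ti] < t1:
            tau = times[ti] - t0
            c = 0.0
            for j in range(3):
                lj = lam[j]
                bj = vinv[j, 0] * rate
                if lj == 0.0:
                    zj = z0[j] + bj * tau
                else:
                    e = np.expm1(lj * tau)
                    zj = z0[j] * (e + 1.0) + bj * e / lj
                c += vec[0, j] * zj
            out[ti] = c / v1 if c > 0.0 else 0.0
            ti += 1
        if seg + 1 < nseg:
            dt = t1 - t0
            for j in range(3):
                lj = lam[j]
                bj = vinv[j, 0] * rate
                if lj == 0.0:
                    z0[j] = z0[j] + bj * dt
                else:
                    e = np.expm1(lj * dt)
                    z0[j] = z0[j] * (e + 1.0) + bj * e / lj
            state = vec @ z0
    return 0


@njit(cache=True, error_model="numpy")
def _chol(h, low):
    """In-place Cholesky of a small SPD matrix; returns False if not PD."""
    d = h.shape[0]
    for i in range(d):
        for j in range(d):
            low[i, j] = 0.0
    for i in range(d):
        for j in range(i + 1):
            s = h[i, j]
            for k in range(j):
                s -= low[i, k] * low[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                low[i, i] = np.sqrt(s)
            else:
                low[i, j] = s / low[j, j]
    return True


@njit(cache=True, error_model="numpy")
def _chol_solve(low, rhs, x):
    d = low.shape[0]
    # forward then backward substitution
    for i in range(d):
        s = rhs[i]
        for k in range(i):
            s -= low[i, k] * x[k]
        x[i] = s / low[i, i]
    for i in range(d - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, d):
            s -= low[k, i] * x[k]
        x[i] = s / low[i, i]


@njit(cache=True, error_model="numpy")
def _subject_m2ll_kernel(
    typ,
    re_idx,
    om2,
    cv,
    sd,
    y,
    times,
    knots,
    rates,
    bolus_t,
    bolus_a,
    inner_tol,
    inner_maxiter,
    eta_out,
):
    """-2 log marginal likelihood of one subject by Laplace approximation."""
    n = y.shape[0]
    d = re_idx.shape[0]
    cv2 = cv * cv
    sd2 = sd * sd
    step_fd = 1e-4

    p = np.empty(6)
    f = np.empty(n)
    if d == 0:
        _conc_profile(typ, knots, rates, bolus_t, bolus_a, times, f)
        total = 0.0
        for i in range(n):
            g2 = f[i] * f[i] * cv2 + sd2
            if g2 <= 0.0 or not np.isfinite(f[i]):
                return np.inf
            r = y[i] - f[i]
            total += r * r / g2 + np.log(g2)
        return total + n * _LOG_2PI

    eta = np.zeros(d)
    jac = np.empty((n, d))
    fp = np.empty(n)
    grad = np.empty(d)
    hess = np.empty((d, d))
    hdamp = np.empty((d, d))
    low = np.empty((d, d))
    delta = np.empty(d)
    cand = np.empty(d)
    f_c = np.empty(n)
    jac_c = np.empty((n, d))

    def _pset(e):
        for k in range(6):
            p[k] = typ[k]
        for j in range(d):
            p[re_idx[j]] *= np.exp(e[j])

    def _h_of(e, fbuf):
        _pset(e)
        _conc_profile(p, knots, rates, bolus_t, bolus_a, times, fbuf)
        h = 0.0
        for i in range(n):
            g2 = fbuf[i] * fbuf[i] * cv2 + sd2
            if g2 <= 0.0 or not np.isfinite(fbuf[i]):
                return np.inf
            r = y[i] - fbuf[i]
            h += r * r / g2 + np.log(g2)
        for j in range(d):
            h += e[j] * e[j] / om2[j]
        return h

    def _jac_at(e, fbase, jbuf):
        for j in range(d):
            for k in range(d):
                cand[k] = e[k]
            cand[j] += step_fd
            _pset(cand)
            _conc_profile(p, knots, rates, bolus_t, bolus_a, times, fp)
            for i in range(n):
                jbuf[i, j] = (fp[i] - fbase[i]) / step_fd

    h_val = _h_of(eta, f)
    if not np.isfinite(h_val):
        return np.inf
    _jac_at(eta, f, jac)

    damping = 0.0
    for _ in range(inner_maxiter):
        # weighted Gauss-Newton system at the current iterate
        for j in range(d):
            grad[j] = eta[j] / om2[j]
            for k in range(d):
                hess[j, k] = 0.0
            hess[j, j] = 1.0 / om2[j]
        for i in range(n):
            g2 = f[i] * f[i] * cv2 + sd2
            w = 1.0 / g2
            r = y[i] - f[i]
            # dh/df includes the interaction terms from g2(f): the residual
            # weight and the log-variance penalty both move with f
            dh_df = -r * w + f[i] * cv2 * w * (1.0 - r * r * w)
            for j in range(d):
                grad[j] += jac[i, j] * dh_df
                for k in range(j + 1):
                    hess[j, k] += jac[i, j] * w * jac[i, k]
        for j in range(d):
            for k in range(j + 1, d):
                hess[j, k] = hess[k, j]
        for j in range(d):
            for k in range(d):
                hdamp[j, k] = hess[j, k]
            hdamp[j, j] += damping * hess[j, j]
        if not _chol(hdamp, low):
            return np.inf
        for j in range(d):
            delta[j] = -grad[j]
        _chol_solve(low, delta.copy(), delta)
        dec = 0.0
        mx = 0.0
        for j in range(d):
            dec -= grad[j] * delta[j]
            if np.abs(delta[j]) > mx:
                mx = np.abs(delta[j])
        if dec < 1e-9 or mx < inner_tol:
            break
        alpha = 1.0
        accepted = False
        h_new = np.inf
        for _ls in range(6):
            for j in range(d):
                cand[j] = eta[j] + alpha * delta[j]
            h_new = _h_of(cand, f_c)
            if h_new <= h_val + 1e-12 * (1.0 + np.abs(h_val)):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            if dec < 1e-6:
                break
            damping = max(10.0 * damping, 1.0)
            if damping > 1e4:
                break
            continue
        damping = damping / 4.0
        if damping < 1e-3:
            damping = 0.0
        moved = 0.0
        for j in range(d):
            if np.abs(alpha * delta[j]) > moved:
                moved = np.abs(alpha * delta[j])
        gained = h_val - h_new
        for j in range(d):
            eta[j] = cand[j]
        for i in range(n):
            f[i] = f_c[i]
        h_val = h_new
        _jac_at(eta, f, jac)
        if moved < inner_tol or gained < 1e-9:
            break

    for j in range(d):
        eta_out[j] = eta[j]
    # Laplace: log-determinant of the Gauss-Newton curvature at the mode
    for j in range(d):
        for k in range(d):
            hess[j, k] = 0.0
        hess[j, j] = 1.0 / om2[j]
    total = 0.0
    for i in range(n):
        g2 = f[i] * f[i] * cv2 + sd2
        if g2 <= 0.0 or not np.isfinite(f[i]):
            return np.inf
        w = 1.0 / g2
        r = y[i] - f[i]
        total += r * r / g2 + np.log(g2)
        for j in range(d):
            for k in range(j + 1):
                hess[j, k] += jac[i, j] * w * jac[i, k]
    for j in range(d):
        for k in range(j + 1, d):
            hess[j, k] = hess[k, j]
    if not _chol(hess, low):
        return np.inf
    logdet = 0.0
    for j in range(d):
        logdet += 2.0 * np.log(low[j, j])
        total += eta[j] * eta[j] / om2[j] + np.log(om2[j])
    return total + n * _LOG_2PI + logdet


@njit(cache=True, error_model="numpy")
def population_m2ll(
    typ_all,
    re_idx,
    om2,
    cv,
    sd,
    y_flat,
    times_flat,
    obs_off,
    knots_flat,
    rates_flat,
    seg_off,
    bolus_t_flat,
    bolus_a_flat,
    bolus_off,
    inner_tol,
    inner_maxiter,
    etas_out,
):
    """Sum of per-subject Laplace -2LL contributions; +inf if any subject fails."""
    n_sub = typ_all.shape[0]
    total = 0.0
    for s in range(n_sub):
        o0, o1 = obs_off[s], obs_off[s + 1]
        s0, s1 = seg_off[s], seg_off[s + 1]
        b0, b1 = bolus_off[s], bolus_off[s + 1]
        contrib = _subject_m2ll_kernel(
            typ_all[s],
            re_idx,
            om2,
            cv,
            sd,
            y_flat[o0:o1],
            times_flat[o0:o1],
            knots_flat[s0:s1],
            rates_flat[s0:s1],
            bolus_t_flat[b0:b1],
            bolus_a_flat[b0:b1],
            inner_tol,
            inner_maxiter,
            etas_out[s],
        )
        if not np.isfinite(contrib):
            return np.inf
        total += contrib
    return total
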