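"""Batched fixed-step RK4 integrator for the neural + balloon forward model.

This is the hot path of model inversion: finite-difference sensitivities
need the forward model evaluated at dozens of perturbed parameter vectors
per iteration, so the integrator runs over a whole batch of parameter sets
in one compiled call.  The update rule is identical to the reference
implementation in :mod:`cmcdcm.generative` (neural RK4 with bin-constant
input, then a balloon RK4 step using midpoint-interpolated neural
activity); a cross-consistency test keeps the two paths in agreement.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rk4_bold_batch"]


@njit(cache=True)
def _neural_deriv(A_b, u_t, d_idx, d_val_b, y, out):
    R = y.shape[0]
    for i in range(R):
        acc = u_t[i]
        for j in range(R):
            acc += A_b[i, j] * y[j]
        out[i] = acc
    for e in range(d_idx.shape[0]):
        m = d_idx[e, 0]
        s = d_idx[e, 1]
        t = d_idx[e, 2]
        out[t] += d_val_b[e] * y[m] * y[s]


@njit(cache=True)
def _hemo_deriv(s, f, v, q, y, kappa, gamma, tau, alpha, rho, out):
    fv = v ** (1.0 / alpha)
    e = 1.0 - (1.0 - rho) ** (1.0 / f)
    out[0] = y - kappa * s - gamma * (f - 1.0)
    out[1] = s
    out[2] = (f - fv) / tau
    out[3] = (f * e / rho - fv * q / v) / tau


@njit(cache=True)
def rk4_bold_batch(
    A, U, d_idx, d_val, dt, scan_stride, n_scans,
    kappa, gamma, tau, alpha, rho, v0, bound,
):
    """Integrate B parameter sets and sample BOLD at scan times.

    A: (B, R, R) connectivity; U: (B, R, T) precomputed drive C·x(t);
    d_idx: (n_d, 3) modulator/source/target indices; d_val: (B, n_d).
    Returns (bold (B, n_scans, R) in percent signal change, ok (B,) flags;
    a failed batch member holds zeros).
    """
    B, R, T = U.shape
    k1c = 7.0 * rho
    k2c = 2.0
    k3c = 2.0 * rho - 0.2
    out = np.zeros((B, n_scans, R))
    ok = np.ones(B, np.bool_)

    y = np.zeros(R)
    ytmp = np.zeros(R)
    ynew = np.zeros(R)
    ymid = np.zeros(R)
    kn1 = np.zeros(R)
    kn2 = np.zeros(R)
    kn3 = np.zeros(R)
    kn4 = np.zeros(R)
    st = np.zeros(4)
    sttmp = np.zeros(4)
    kh1 = np.zeros(4)
    kh2 = np.zeros(4)
    kh3 = np.zeros(4)
    kh4 = np.zeros(4)

    for b in range(B):
        for i in range(R):
            y[i] = 0.0
        s_arr = np.zeros(R)
        f_arr = np.ones(R)
        v_arr = np.ones(R)
        q_arr = np.ones(R)
        ksc = 0
        good = True
        for t in range(T):
            if t % scan_stride == 0 and ksc < n_scans:
                for i in range(R):
                    out[b, ksc, i] = 100.0 * v0 * (
                        k1c * (1.0 - q_arr[i])
                        + k2c * (1.0 - q_arr[i] / v_arr[i])
                        + k3c * (1.0 - v_arr[i])
                    )
                ksc += 1
            # --- neural RK4 step (input constant over the bin)
            u_t = U[b, :, t]
            A_b = A[b]
            d_b = d_val[b]
            _neural_deriv(A_b, u_t, d_idx, d_b, y, kn1)
            for i in range(R):
                ytmp[i] = y[i] + 0.5 * dt * kn1[i]
            _neural_deriv(A_b, u_t, d_idx, d_b, ytmp, kn2)
            for i in range(R):
                ytmp[i] = y[i] + 0.5 * dt * kn2[i]
            _neural_deriv(A_b, u_t, d_idx, d_b, ytmp, kn3)
            for i in range(R):
                ytmp[i] = y[i] + dt * kn3[i]
            _neural_deriv(A_b, u_t, d_idx, d_b, ytmp, kn4)
            for i in range(R):
                ynew[i] = y[i] + (dt / 6.0) * (
                    kn1[i] + 2.0 * kn2[i] + 2.0 * kn3[i] + kn4[i]
                )
                ymid[i] = 0.5 * (y[i] + ynew[i])
            # --- balloon RK4 step per region (neural input interpolated)
            for i in range(R):
                st[0] = s_arr[i]
                st[1] = f_arr[i]
                st[2] = v_arr[i]
                st[3] = q_arr[i]
                _hemo_deriv(st[0], st[1], st[2], st[3], y[i],
                            kappa, gamma, tau, alpha, rho, kh1)
                for n in range(4):
                    sttmp[n] = st[n] + 0.5 * dt * kh1[n]
                _hemo_deriv(sttmp[0], sttmp[1], sttmp[2], sttmp[3], ymid[i],
                            kappa, gamma, tau, alpha, rho, kh2)
                for n in range(4):
                    sttmp[n] = st[n] + 0.5 * dt * kh2[n]
                _hemo_deriv(sttmp[0], sttmp[1], sttmp[2], sttmp[3], ymid[i],
                            kappa, gamma, tau, alpha, rho, kh3)
                for n in range(4):
                    sttmp[n] = st[n] + dt * kh3[n]
                _hemo_deriv(sttmp[0], sttmp[1], sttmp[2], sttmp[3], ynew[i],
                            kappa, gamma, tau, alpha, rho, kh4)
                s_arr[i] = st[0] + (dt / 6.0) * (kh1[0] + 2.0 * kh2[0] + 2.0 * kh3[0] + kh4[0])
                f_arr[i] = st[1] + (dt / 6.0) * (kh1[1] + 2.0 * kh2[1] + 2.0 * kh3[1] + kh4[1])
                v_arr[i] = st[2] + (dt / 6.0) * (kh1[2] + 2.0 * kh2[2] + 2.0 * kh3[2] + kh4[2])
                q_arr[i] = st[3] + (dt / 6.0) * (kh1[3] + 2.0 * kh2[3] + 2.0 * kh3[3] + kh4[3])
            # --- validity checks
            for i in range(R):
                y[i] = ynew[i]
                if not (np.isfinite(y[i]) and abs(y[i]) <= bound):
                    good = False
                if not (np.isfinite(s_arr[i]) and np.isfinite(q_arr[i])):
                    good = False
                if not (f_arr[i] > 0.0 and v_arr[i] > 0.0 and q_arr[i] > 0.0):
                    good = False
                # balloon validity box: ratios to rest are O(1); beyond 100
                # the hemodynamic model has left its domain
                if f_arr[i] > 100.0 or v_arr[i] > 100.0 or q_arr[i] > 100.0:
                    good = False
            if not good:
                ok[b] = False
                for k in range(n_scans):
                    for i in range(R):
                        out[b, k, i] = 0.0
                break
    return out, ok
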