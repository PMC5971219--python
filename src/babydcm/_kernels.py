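"""Compiled integration kernel for the neural + haemodynamic state system.

A single fixed-step RK4 loop over a batch of parameter sets: the batch axis
serves both simulation (batch of 1) and finite-difference Jacobians during
inversion (one perturbed parameter vector per batch row).  The inner loops
are allocation-free; all stage buffers are reused across time steps.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _stage(y, A, B, C, u, kappa_s, gamma, inv_tau, inv_alpha, inv_E0, log_1mE0, dy):
    """Derivative of the stacked state y = (z, s, f, v, q) per region,
    written into dy.  y has shape (5, n).  The haemodynamic constants come
    pre-inverted/logged (inv_tau = 1/tau, inv_alpha = 1/alpha,
    inv_E0 = 1/E0, log_1mE0 = ln(1 - E0)) so the balloon nonlinearities
    cost two exponentials and one logarithm per region."""
    n = A.shape[0]
    m = u.shape[0]
    for i in range(n):
        acc = 0.0
        for j in range(n):
            a_ij = A[i, j]
            for k in range(m):
                a_ij += u[k] * B[k, i, j]
            acc += a_ij * y[0, j]
        for k in range(m):
            acc += C[i, k] * u[k]
        dy[0, i] = acc
        z = y[0, i]
        s = y[1, i]
        f = y[2, i]
        v = y[3, i]
        q = y[4, i]
        dy[1, i] = z - kappa_s[i] * s - gamma[i] * (f - 1.0)
        dy[2, i] = s
        fv = np.exp(inv_alpha[i] * np.log(v))
        dy[3, i] = (f - fv) * inv_tau[i]
        ef = 1.0 - np.exp(log_1mE0[i] / f)
        dy[4, i] = (f * ef * inv_E0[i] - fv * q / v) * inv_tau[i]


@njit(cache=True, fastmath=True)
def integrate_batch(A, B, C, kappa_s, gamma, tau, alpha, E0, U, dt):
    """Integrate the stacked bilinear-neural + balloon system.

    Parameters are batched on the leading axis: A (K,n,n), B (K,m,n,n),
    C (K,n,m), haemodynamic vectors (K,n).  U is (m,T) input values sampled
    on the integration grid (piecewise constant per step).  Returns
    z, v, q arrays of shape (K, n, T) recorded at every step, plus a flag
    array marking batch rows whose states blew up or left the positive
    domain.
    """
    K, n, _ = A.shape
    m, T = U.shape
    z_out = np.zeros((K, n, T))
    v_out = np.ones((K, n, T))
    q_out = np.ones((K, n, T))
    bad = np.zeros(K, dtype=np.uint8)
    y = np.empty((5, n))
    yt = np.empty((5, n))
    k1 = np.empty((5, n))
    k2 = np.empty((5, n))
    k3 = np.empty((5, n))
    k4 = np.empty((5, n))
    for kb in range(K):
        Ak = A[kb]
        Bk = B[kb]
        Ck = C[kb]
        ks = kappa_s[kb]
        ga = gamma[kb]
        ta = 1.0 / tau[kb]
        al = 1.0 / alpha[kb]
        e0 = 1.0 / E0[kb]
        le = np.log(1.0 - E0[kb])
        for i in range(n):
            y[0, i] = 0.0
            y[1, i] = 0.0
            y[2, i] = 1.0
            y[3, i] = 1.0
            y[4, i] = 1.0
        for t in range(T):
            u = U[:, t]
            _stage(y, Ak, Bk, Ck, u, ks, ga, ta, al, e0, le, k1)
            for a in range(5):
                for i in range(n):
                    yt[a, i] = y[a, i] + 0.5 * dt * k1[a, i]
            _stage(yt, Ak, Bk, Ck, u, ks, ga, ta, al, e0, le, k2)
            for a in range(5):
                for i in range(n):
                    yt[a, i] = y[a, i] + 0.5 * dt * k2[a, i]
            _stage(yt, Ak, Bk, Ck, u, ks, ga, ta, al, e0, le, k3)
            for a in range(5):
                for i in range(n):
                    yt[a, i] = y[a, i] + dt * k3[a, i]
            _stage(yt, Ak, Bk, Ck, u, ks, ga, ta, al, e0, le, k4)
            c = dt / 6.0
            ok = True
            for a in range(5):
                for i in range(n):
                    y[a, i] += c * (
                        k1[a, i] + 2.0 * k2[a, i] + 2.0 * k3[a, i] + k4[a, i]
                    )
            for i in range(n):
                if (
                    np.abs(y[0, i]) > 1e3
                    or y[2, i] <= 1e-6
                    or y[3, i] <= 1e-6
                    or y[4, i] <= 1e-6
                    or not np.isfinite(y[3, i])
                ):
                    ok = False
                z_out[kb, i, t] = y[0, i]
                v_out[kb, i, t] = y[3, i]
                q_out[kb, i, t] = y[4, i]
            if not ok:
                bad[kb] = 1
                break
    return z_out, v_out, q_out, bad


@njit(cache=True, fastmath=True)
def integrate_epoch_average(
    A, B, C, kappa_s, gamma, tau, alpha, E0, U, dt,
    epoch_start, epoch_cond, n_cond, window, bold_consts,
):
    """Integrate the full session and accumulate per-condition epoch
    averages of venous volume, deoxyhaemoglobin and the BOLD signal.

    ``epoch_start`` holds the first output sample of each epoch window,
    ``epoch_cond`` its condition index; ``window`` is the epoch length in
    samples.  Returns (v_avg, q_avg, bold_avg) of shape
    (K, n_cond, n, window) plus per-condition epoch counts and the
    instability flags.  Averaging inside the kernel keeps the memory
    footprint independent of the session length.
    """
    K, n, _ = A.shape
    m, T = U.shape
    nE = epoch_start.shape[0]
    v_avg = np.zeros((K, n_cond, n, window))
    q_avg = np.zeros((K, n_cond, n, window))
    b_avg = np.zeros((K, n_cond, n, window))
    counts = np.zeros(n_cond, dtype=np.int64)
    for e in range(nE):
        counts[epoch_cond[e]] += 1
    bad = np.zeros(K, dtype=np.uint8)
    V0 = bold_consts[0]
    bk1 = bold_consts[1]
    bk2 = bold_consts[2]
    bk3 = bold_consts[3]
    y = np.empty((5, n))
    yt = np.empty((5, n))
    k1 = np.empty((5, n))
    k2 = np.empty((5, n))
    k3 = np.empty((5, n))
    k4 = np.empty((5, n))
    for kb in range(K):
        Ak = A[kb]
        Bk = B[kb]
        Ck = C[kb]
        ks = kappa_s[kb]
        ga = gamma[kb]
        ta = 1.0 / tau[kb]
        al = 1.0 / alpha[kb]
        e0 = 1.0 / E0[kb]
        le = np.log(1.0 - E0[kb])
        for i in range(n):
            y[0, i] = 0.0
            y[1, i] = 0.0
            y[2, i] = 1.0
            y[3, i] = 1.0
            y[4, i] = 1.0
        ok = True
        for t in range(T):
            u = U[:, t]
            _stage(y, Ak, Bk, Ck, u, ks, ga, ta, al, e0, le, k1)
            for a in range(5):
                for i in range(n):
                    yt[a, i] = y[a, i] + 0.5 * dt * k1[a, i]
            _stage(yt, Ak, Bk, Ck, u, ks, ga, ta, al, e0, le, k2)
            for a in range(5):
                for i in range(n):
                    yt[a, i] = y[a, i] + 0.5 * dt * k2[a, i]
            _stage(yt, Ak, Bk, Ck, u, ks, ga, ta, al, e0, le, k3)
            for a in range(5):
                for i in range(n):
                    yt[a, i] = y[a, i] + dt * k3[a, i]
            _stage(yt, Ak, Bk, Ck, u, ks, ga, ta, al, e0, le, k4)
            c = dt / 6.0
            for a in range(5):
                for i in range(n):
                    y[a, i] += c * (
                        k1[a, i] + 2.0 * k2[a, i] + 2.0 * k3[a, i] + k4[a, i]
                    )
            for i in range(n):
                if (
                    np.abs(y[0, i]) > 1e3
                    or y[2, i] <= 1e-6
                    or y[3, i] <= 1e-6
                    or y[4, i] <= 1e-6
                    or not np.isfinite(y[3, i])
                ):
                    ok = False
            if not ok:
                bad[kb] = 1
                break
            for e in range(nE):
                off = t - epoch_start[e]
                if 0 <= off < window:
                    ce = epoch_cond[e]
                    for i in range(n):
                        vi = y[3, i]
                        qi = y[4, i]
                        v_avg[kb, ce, i, off] += vi
                        q_avg[kb, ce, i, off] += qi
                        b_avg[kb, ce, i, off] += V0 * (
                            bk1 * (1.0 - qi)
                            + bk2 * (1.0 - qi / vi)
                            + bk3 * (1.0 - vi)
                        )
    for cidx in range(n_cond):
        if counts[cidx] > 0:
            for kb in range(K):
                for i in range(n):
                    for off in range(window):
                        v_avg[kb, cidx, i, off] /= counts[cidx]
                        q_avg[kb, cidx, i, off] /= counts[cidx]
                        b_avg[kb, cidx, i, off] /= counts[cidx]
    return v_avg, q_avg, b_avg, counts, bad
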