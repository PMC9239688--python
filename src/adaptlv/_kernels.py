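"""Fixed-step RK4 kernels for the treatment-modulated Lotka-Volterra system.

These kernels back the fitting forward model and the closed-loop protocol
simulator, where many thousands of short integrations are needed.  They are
cross-checked in the test suite against the adaptive-step reference
integrator (`model_core.integrate`) and against the closed-form logistic
solution.  Populations are clamped non-negative after every step: cell
counts are physical.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=False)
def _rhs_into(x, out, lam, r, K, alpha, drop, beta):
    n = x.shape[0]
    for i in range(n):
        keff = K[i] * (1.0 - drop[i] * lam)
        s = 0.0
        for j in range(n):
            s += alpha[i, j] * x[j]
        out[i] = beta * r[i] * x[i] * (1.0 - s / keff)


@njit(cache=False)
def lv_rhs(x, lam, r, K, alpha, drop, beta):
    """dx_i/dt = beta * r_i * x_i * (1 - sum_j alpha_ij x_j / K_i,eff).

    K_i,eff = K_i * (1 - drop_i * lam); lam is the treatment indicator.
    """
    out = np.empty(x.shape[0])
    _rhs_into(x, out, lam, r, K, alpha, drop, beta)
    return out


@njit(cache=False)
def _rk4_inplace(y, h, n_steps, lam, r, K, alpha, drop, beta, k1, k2, k3, k4, tmp):
    n = y.shape[0]
    for _ in range(n_steps):
        _rhs_into(y, k1, lam, r, K, alpha, drop, beta)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * h * k1[i]
        _rhs_into(tmp, k2, lam, r, K, alpha, drop, beta)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * h * k2[i]
        _rhs_into(tmp, k3, lam, r, K, alpha, drop, beta)
        for i in range(n):
            tmp[i] = y[i] + h * k3[i]
        _rhs_into(tmp, k4, lam, r, K, alpha, drop, beta)
        for i in range(n):
            y[i] = y[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if y[i] < 0.0:
                y[i] = 0.0


@njit(cache=False)
def rk4_advance(x, h, n_steps, lam, r, K, alpha, drop, beta):
    """Advance state by n_steps classical RK4 steps of size h. Returns new state."""
    n = x.shape[0]
    y = x.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    _rk4_inplace(y, h, n_steps, lam, r, K, alpha, drop, beta, k1, k2, k3, k4, tmp)
    return y


@njit(cache=False)
def rk4_dense(x, dt_out, n_out, substeps, lam, r, K, alpha, drop, beta):
    """Advance n_out output intervals of length dt_out, `substeps` RK4 steps each.

    Returns an (n_out, n_types) array of the states at t0 + dt_out * (1..n_out).
    """
    n = x.shape[0]
    out = np.empty((n_out, n))
    y = x.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    for k in range(n_out):
        _rk4_inplace(y, dt_out / substeps, substeps, lam, r, K, alpha, drop, beta, k1, k2, k3, k4, tmp)
        out[k] = y
    return out


@njit(cache=False)
def sim_at_times(x0, seg_starts, seg_on, eval_times, h_max, r, K, alpha, drop, beta):
    """Integrate under a piecewise-constant treatment schedule, sampling states.

    seg_starts: ascending segment start times; segment k is active on
    [seg_starts[k], seg_starts[k+1]) and the last segment extends to +inf.
    seg_on: treatment flag per segment (0/1).  x0 is the state at
    seg_starts[0].  eval_times must be ascending with
    eval_times[0] >= seg_starts[0].  Integration is restarted exactly at
    every segment boundary so the carrying-capacity discontinuity is hit on
    the nose.
    """
    n = x0.shape[0]
    x = x0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    t = seg_starts[0]
    n_eval = eval_times.shape[0]
    out = np.empty((n_eval, n))
    si = 0
    for ei in range(n_eval):
        te = eval_times[ei]
        while True:
            if si + 1 < seg_starts.shape[0] and seg_starts[si + 1] < te:
                tb = seg_starts[si + 1]
                lam = 1.0 if seg_on[si] else 0.0
                if tb > t:
                    n_steps = int(np.ceil((tb - t) / h_max))
                    if n_steps < 1:
                        n_steps = 1
                    _rk4_inplace(x, (tb - t) / n_steps, n_steps, lam, r, K, alpha, drop, beta,
                                 k1, k2, k3, k4, tmp)
                t = tb
                si += 1
            else:
                lam = 1.0 if seg_on[si] else 0.0
                if te > t:
                    n_steps = int(np.ceil((te - t) / h_max))
                    if n_steps < 1:
                        n_steps = 1
                    _rk4_inplace(x, (te - t) / n_steps, n_steps, lam, r, K, alpha, drop, beta,
                                 k1, k2, k3, k4, tmp)
                    t = te
                out[ei] = x
                break
    return out
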