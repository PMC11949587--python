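"""Jitted adaptive Runge-Kutta 4(5) integrator for the Hopf network model.

Implements the Dormand-Prince embedded pair with the standard 4th-order
dense-output interpolant and a PI-free step controller (error ** -1/5 with a
safety factor), specialized to the coupled Stuart-Landau system so that the
whole integration loop runs inside numba. The state is stored as a real
vector ``[x_1..x_N, y_1..y_N]`` of the oscillators' real and imaginary parts.

Correctness is checked in the test suite against scipy.integrate.solve_ivp
and against a fixed-step classical RK4 reference.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dormand-Prince 4(5) tableau (the pair used by scipy's RK45 / MATLAB ode45)
_A = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0],
        [1 / 5, 0.0, 0.0, 0.0, 0.0],
        [3 / 40, 9 / 40, 0.0, 0.0, 0.0],
        [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0],
        [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0],
        [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656],
    ]
)
_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84])
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0])
# difference between the 5th- and 4th-order weights (7 stages incl. FSAL)
_E = np.array(
    [71 / 57600, 0.0, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40]
)
# 4th-order dense-output interpolation matrix (Shampine)
_P = np.array(
    [
        [1.0, -8048581381 / 2820520608, 8663915743 / 2820520608, -12715105075 / 11282082432],
        [0.0, 0.0, 0.0, 0.0],
        [0.0, 131558114200 / 32700410799, -68118460800 / 10900136933, 87487479700 / 32700410799],
        [0.0, -1754552775 / 470086768, 14199869525 / 1410260304, -10690763975 / 1880347072],
        [0.0, 127303824393 / 49829197408, -318862633887 / 49829197408, 701980252875 / 199316789632],
        [0.0, -282668133 / 205662961, 2019193451 / 616988883, -1453857185 / 822651844],
        [0.0, 40617522 / 29380423, -110615467 / 29380423, 69997945 / 29380423],
    ]
)

_SAFETY = 0.9
_MIN_FACTOR = 0.2
_MAX_FACTOR = 10.0


@njit(cache=True)
def hopf_rhs(u, W, omega, K, lam, C, gain):
    """Time derivative of the coupled Hopf system in real coordinates.

    dz_i/dt = z_i (lambda + i omega_i - |z_i|^2) + g_i K tanh(C sum_j w_ij x_j)
    with z_i = x_i + i y_i; the coupling acts through real parts only.
    """
    N = omega.shape[0]
    x = u[:N]
    y = u[N:]
    coupling = gain * (K * np.tanh(C * (W @ x)))
    r2 = x * x + y * y
    du = np.empty(2 * N)
    du[:N] = x * (lam - r2) - omega * y + coupling
    du[N:] = y * (lam - r2) + omega * x
    return du


@njit(cache=True)
def _initial_step(u0, f0, W, omega, K, lam, C, gain, rtol, atol):
    # scipy-style heuristic for the first step size
    sc = atol + rtol * np.abs(u0)
    d0 = np.sqrt(np.mean((u0 / sc) ** 2))
    d1 = np.sqrt(np.mean((f0 / sc) ** 2))
    h0 = 1e-6 if (d0 < 1e-5 or d1 < 1e-5) else 0.01 * d0 / d1
    u1 = u0 + h0 * f0
    f1 = hopf_rhs(u1, W, omega, K, lam, C, gain)
    d2 = np.sqrt(np.mean(((f1 - f0) / sc) ** 2)) / h0
    if d1 <= 1e-15 and d2 <= 1e-15:
        h1 = max(1e-6, h0 * 1e-3)
    else:
        h1 = (0.01 / max(d1, d2)) ** 0.2
    return min(100 * h0, h1)


@njit(cache=True)
def integrate_hopf(u0, t0, t1, t_out, W, omega, K, lam, C, gain, rtol, atol):
    """Integrate from t0 to t1, returning the state at the times ``t_out``.

    Output times must be increasing and lie in [t0, t1]. Returns
    ``(out, status, t_fail)`` where status 0 means success, 1 non-finite
    state, 2 step size underflow.
    """
    n = u0.shape[0]
    t = t0
    u = u0.copy()
    f = hopf_rhs(u, W, omega, K, lam, C, gain)
    h = _initial_step(u, f, W, omega, K, lam, C, gain, rtol, atol)
    stages = np.empty((7, n))
    out = np.empty((t_out.shape[0], n))
    io = 0
    # fill any output points at exactly t0
    while io < t_out.shape[0] and t_out[io] <= t0:
        out[io] = u
        io += 1
    err_exp = -0.2
    min_step = 1e-13 * max(abs(t0), abs(t1), 1.0)
    while t < t1:
        if h < min_step:
            return out, 2, t
        if h > t1 - t:
            h = t1 - t
        stages[0] = f
        for s in range(1, 6):
            du = np.zeros(n)
            for j in range(s):
                du += _A[s, j] * stages[j]
            stages[s] = hopf_rhs(u + h * du, W, omega, K, lam, C, gain)
        du = np.zeros(n)
        for j in range(6):
            du += _B[j] * stages[j]
        u_new = u + h * du
        if not np.all(np.isfinite(u_new)):
            return out, 1, t
        f_new = hopf_rhs(u_new, W, omega, K, lam, C, gain)
        stages[6] = f_new
        err_vec = np.zeros(n)
        for j in range(7):
            err_vec += _E[j] * stages[j]
        err_vec *= h
        sc = atol + rtol * np.maximum(np.abs(u), np.abs(u_new))
        err = np.sqrt(np.mean((err_vec / sc) ** 2))
        if err <= 1.0:
            # interpolate dense output at grid points inside (t, t + h]
            while io < t_out.shape[0] and t_out[io] <= t + h + 1e-15:
                s_frac = (t_out[io] - t) / h
                powers = np.empty(4)
                p = s_frac
                for q in range(4):
                    powers[q] = p
                    p *= s_frac
                coef = _P @ powers
                ui = u.copy()
                for j in range(7):
                    ui += (h * coef[j]) * stages[j]
                out[io] = ui
                io += 1
            t += h
            u = u_new
            f = f_new
            factor = _MAX_FACTOR if err == 0.0 else min(_MAX_FACTOR, _SAFETY * err**err_exp)
        else:
            factor = max(_MIN_FACTOR, _SAFETY * err**err_exp)
        h *= factor
    # numerical slop: any trailing output points at t1
    while io < t_out.shape[0]:
        out[io] = u
        io += 1
    return out, 0, t
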