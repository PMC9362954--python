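"""Compiled fixed-step RK4 kernels.

Grid scans integrate tens of thousands of trajectories for up to 2e6 steps
each, so the inner loop is JIT-compiled with numba.  Status codes returned by
the kernels: 1 = converged (step-to-step change below tolerance), 0 = step
budget exhausted, -1 = non-finite state encountered (the continuous system is
bounded, so this indicates an invalid unchecked parameter set or a bug).
"""

import math

import numba
import numpy as np


@numba.njit(cache=True, fastmath=False)
def _deriv(x, y, xi, beta, eta, p, mu, s1, s2):
    z = 1.0 - x - y
    fc = (1.0 - s1) * x - s1 * y + s1
    fd = (beta - s2) * x + ((2.0 * p - 1.0) * eta - s2) * y + s2
    dx = x * (z * fc - xi) + mu * (y - x)
    dy = y * (z * fd - xi) + mu * (x - y)
    return dx, dy


@numba.njit(cache=True, fastmath=False)
def _rk4_step(x, y, xi, beta, eta, p, mu, s1, s2, dt):
    k1x, k1y = _deriv(x, y, xi, beta, eta, p, mu, s1, s2)
    k2x, k2y = _deriv(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y, xi, beta, eta, p, mu, s1, s2)
    k3x, k3y = _deriv(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y, xi, beta, eta, p, mu, s1, s2)
    k4x, k4y = _deriv(x + dt * k3x, y + dt * k3y, xi, beta, eta, p, mu, s1, s2)
    xn = x + dt * (k1x + 2.0 * k2x + 2.0 * k3x + k4x) / 6.0
    yn = y + dt * (k1y + 2.0 * k2y + 2.0 * k3y + k4y) / 6.0
    return xn, yn


@numba.njit(cache=True, fastmath=False)
def rk4_run(x0, y0, xi, beta, eta, p, mu, s1, s2, dt, max_steps, conv_tol):
    """Integrate to the final state.  Returns (x, y, steps_taken, status)."""
    x, y = x0, y0
    for n in range(max_steps):
        xn, yn = _rk4_step(x, y, xi, beta, eta, p, mu, s1, s2, dt)
        if not (math.isfinite(xn) and math.isfinite(yn)):
            return x, y, n + 1, -1
        dx = abs(xn - x)
        dy = abs(yn - y)
        x, y = xn, yn
        if conv_tol > 0.0 and dx < conv_tol and dy < conv_tol:
            return x, y, n + 1, 1
    return x, y, max_steps, 0


@numba.njit(cache=True, fastmath=False)
def rk4_record(x0, y0, xi, beta, eta, p, mu, s1, s2, dt, max_steps, conv_tol, stride):
    """Integrate while recording every ``stride``-th state (and the last).

    Returns (times, xs, ys, count, steps_taken, status); the first record is
    the initial condition at t = 0.
    """
    cap = max_steps // stride + 2
    ts = np.empty(cap)
    xs = np.empty(cap)
    ys = np.empty(cap)
    ts[0] = 0.0
    xs[0] = x0
    ys[0] = y0
    count = 1
    x, y = x0, y0
    steps = 0
    status = 0
    for n in range(max_steps):
        xn, yn = _rk4_step(x, y, xi, beta, eta, p, mu, s1, s2, dt)
        steps = n + 1
        if not (math.isfinite(xn) and math.isfinite(yn)):
            status = -1
            break
        dx = abs(xn - x)
        dy = abs(yn - y)
        x, y = xn, yn
        if steps % stride == 0:
            ts[count] = steps * dt
            xs[count] = x
            ys[count] = y
            count += 1
        if conv_tol > 0.0 and dx < conv_tol and dy < conv_tol:
            status = 1
            break
    if status != -1 and (count == 0 or ts[count - 1] != steps * dt):
        ts[count] = steps * dt
        xs[count] = x
        ys[count] = y
        count += 1
    return ts, xs, ys, count, steps, status


@numba.njit(cache=True, fastmath=False, parallel=False)
def rk4_run_batch(x0s, y0s, xis, betas, etas, ps, mus, s1s, s2s, dt, max_steps, conv_tol):
    """Integrate N independent trajectories (parameters per trajectory)."""
    n = x0s.shape[0]
    fx = np.empty(n)
    fy = np.empty(n)
    steps = np.empty(n, dtype=np.int64)
    status = np.empty(n, dtype=np.int64)
    for i in range(n):
        x, y, s, st = rk4_run(
            x0s[i], y0s[i], xis[i], betas[i], etas[i], ps[i], mus[i], s1s[i], s2s[i],
            dt, max_steps, conv_tol,
        )
        fx[i] = x
        fy[i] = y
        steps[i] = s
        status[i] = st
    return fx, fy, steps, status
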