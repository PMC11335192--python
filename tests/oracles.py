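"""Independent oracles used by the test suite.

These deliberately avoid the package's analytic shortcuts: the master
equation is integrated by explicit Euler stepping, and the exponential fit is
checked against an exhaustive SSE grid search.
"""

from __future__ import annotations

import numpy as np

from gatkin.constants import FARADAY_C_PER_MOL, GAS_R_J_PER_MOL_K


def euler_two_state(Qmax, V_half, z_eff, k0, temperature_K, holding_mV, V,
                    duration_s, dt=1e-6):
    """Explicit Euler integration of the two-state master equation
    dp/dt = beta*(1-p) - alpha*p from the holding-potential equilibrium.

    Returns (t, p, current_nA) with current = Qmax * dp/dt.
    """
    sigma = 1000.0 * GAS_R_J_PER_MOL_K * temperature_K / (z_eff * FARADAY_C_PER_MOL)

    def rates(v):
        u = (v - V_half) / sigma
        return k0 * np.exp(+u / 2.0), k0 * np.exp(-u / 2.0)  # alpha, beta

    a_h, b_h = rates(holding_mV)
    p = b_h / (a_h + b_h)
    alpha, beta = rates(V)
    n = int(round(duration_s / dt))
    t = np.arange(n + 1) * dt
    ps = np.empty(n + 1)
    ps[0] = p
    for i in range(n):
        p = p + dt * (beta * (1.0 - p) - alpha * p)
        ps[i + 1] = p
    current = Qmax * np.gradient(ps, dt)
    return t, ps, current


def grid_search_exponential(t, y, t0, A_range, tau_range, base_range,
                            n_A=200, n_tau=200, n_base=50):
    """Exhaustive SSE minimization of y ~ A*exp(-(t-t0)/tau) + base over a
    full (A, tau, base) grid.  The SSE is expanded algebraically so the full
    n_A x n_tau x n_base grid is evaluated exactly but cheaply.

    Returns (A, tau, base, sse) at the grid optimum.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    A_grid = np.linspace(*A_range, n_A)
    tau_grid = np.linspace(*tau_range, n_tau)
    b_grid = np.linspace(*base_range, n_base)
    n = y.size
    Sy = float(np.sum(y * y))
    Sy1 = float(np.sum(y))
    best = (np.nan, np.nan, np.nan, np.inf)
    for tau in tau_grid:
        e = np.exp(-(t - t0) / tau)
        Sye = float(np.sum(y * e))
        See = float(np.sum(e * e))
        Se = float(np.sum(e))
        # SSE(A,b) = Sy - 2A*Sye - 2b*Sy1 + A^2*See + 2Ab*Se + b^2*n
        A = A_grid[:, None]
        b = b_grid[None, :]
        sse = (Sy - 2.0 * A * Sye - 2.0 * b * Sy1 + A * A * See
               + 2.0 * A * b * Se + b * b * n)
        ij = np.unravel_index(np.argmin(sse), sse.shape)
        if sse[ij] < best[3]:
            best = (float(A_grid[ij[0]]), float(tau), float(b_grid[ij[1]]),
                    float(sse[ij]))
    return best


def windowed_mean(values, window):
    """Brute-force truncated centered moving average (smoothing oracle)."""
    values = np.asarray(values, float)
    if window % 2 == 0:
        window += 1
    h = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        lo, hi = max(0, i - h), min(values.size, i + h + 1)
        out[i] = values[lo:hi].mean()
    return out


def depletion_percent_series(rates_pct_per_min, fraction_minutes):
    """Closed-form percent-of-total series for depleting fractional release:
    fraction i releases r_i*fl percent of the content remaining at its start."""
    remaining = 1.0
    out = []
    for r in rates_pct_per_min:
        frac = r * fraction_minutes / 100.0
        out.append(100.0 * frac * remaining)
        remaining *= 1.0 - frac
    return np.asarray(out)
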