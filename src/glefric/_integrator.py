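"""Numba inner loops for the Markovian-embedding GLE integrator.

The generalized Langevin dynamics

    m qdd = -int_0^t Gamma(t-s) qd(s) ds - dU/dq + F_R

with an exponential/damped-oscillating kernel is realised as a memoryless
system in an extended state space:

* each exponential mode (gamma_e, tau_e) becomes one overdamped auxiliary
  coordinate y harmonically coupled to q with spring k = gamma_e/tau_e and
  friction gamma_e, so that eliminating y yields the kernel
  (gamma_e/tau_e) exp(-t/tau_e);
* the oscillating mode (gamma_o, tau_o, omega) becomes one inertial
  auxiliary with mass m_y = gamma_o tau_o / 2, friction gamma_o and spring
  k = gamma_o (1 + omega^2 tau_o^2) / (2 tau_o), whose elimination yields
  the damped-oscillating kernel with decay time tau_o and frequency omega.

Thermal noise enters only through the auxiliary friction channels, so the
fluctuation-dissipation theorem holds for the composite system.  The
integrator is a symmetric BAOAB-style splitting: velocity-Verlet backbone
for the inertial degrees of freedom with exact Ornstein-Uhlenbeck substeps
for the overdamped auxiliaries and for the auxiliary-velocity thermostat.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .potentials import POT_COSINE, POT_FLAT, POT_HARMONIC, POT_QUARTIC


@njit(cache=True, inline="always")
def _pot_force(code, p, tq0, tdq, tF, periodic, period, q):
    if code == POT_FLAT:
        return 0.0
    if code == POT_HARMONIC:
        return -p[0] * (q - p[1])
    if code == POT_QUARTIC:
        u0 = p[0]
        L = p[1]
        return -4.0 * u0 * q * ((q / L) ** 2 - 1.0) / (L * L)
    if code == POT_COSINE:
        return p[0] * np.sin(q) + 2.0 * p[1] * np.sin(2.0 * q) + 3.0 * p[2] * np.sin(3.0 * q)
    # tabulated force, uniform grid, linear interpolation
    n = tF.size
    x = q
    if periodic:
        x = (q - tq0) % period + tq0
        u = (x - tq0) / tdq
        i = int(u)
        if i >= n:
            i = n - 1
        frac = u - i
        j = i + 1
        if j >= n:
            j = 0
        return tF[i] * (1.0 - frac) + tF[j] * frac
    # non-periodic: linear extrapolation from the edge segments
    u = (x - tq0) / tdq
    if u <= 0.0:
        slope = (tF[1] - tF[0]) / 1.0
        return tF[0] + slope * u
    if u >= n - 1:
        slope = tF[n - 1] - tF[n - 2]
        return tF[n - 1] + slope * (u - (n - 1))
    i = int(u)
    frac = u - i
    return tF[i] * (1.0 - frac) + tF[i + 1] * frac


@njit(cache=True)
def run_gle_chunk(
    state,          # [q, v, yo, vyo] mutable
    ye,             # exp auxiliary positions, shape (n_exp,)
    mass, temp, dt,
    ke, ce, se,     # exp springs, OU decay factors, OU noise amplitudes
    has_osc, ko, myo, co, so,   # osc spring, aux mass, velocity OU decay/noise
    code, p, tq0, tdq, tF, periodic, period,
    ne, no,         # normals: (n, n_exp) and (n,)
    out,            # output buffer, length n (or 0 to discard)
):
    """Advance n = ne.shape[0] steps.  Returns -1 on success, else the
    index of the first step at which the state became non-finite."""
    q = state[0]
    v = state[1]
    yo = state[2]
    vyo = state[3]
    n = ne.shape[0]
    n_exp = ye.shape[0]
    half = 0.5 * dt
    record = out.size > 0

    # forces at the start of the step
    F = _pot_force(code, p, tq0, tdq, tF, periodic, period, q)
    for j in range(n_exp):
        F += ke[j] * (ye[j] - q)
    Fo = 0.0
    if has_osc:
        F += ko * (yo - q)
        Fo = ko * (q - yo)

    for i in range(n):
        # B
        v += half * F / mass
        if has_osc:
            vyo += half * Fo / myo
        # A
        q += half * v
        if has_osc:
            yo += half * vyo
        # O: exact OU for overdamped auxiliaries (relax toward current q)
        for j in range(n_exp):
            ye[j] = q + (ye[j] - q) * ce[j] + se[j] * ne[i, j]
        if has_osc:
            vyo = co * vyo + so * no[i]
        # A
        q += half * v
        if has_osc:
            yo += half * vyo
        # B with fresh forces
        F = _pot_force(code, p, tq0, tdq, tF, periodic, period, q)
        for j in range(n_exp):
            F += ke[j] * (ye[j] - q)
        if has_osc:
            F += ko * (yo - q)
            Fo = ko * (q - yo)
        v += half * F / mass
        if has_osc:
            vyo += half * Fo / myo

        if not (q == q and v == v):  # NaN check
            state[0] = q
            state[1] = v
            state[2] = yo
            state[3] = vyo
            return i
        if record:
            out[i] = q

    state[0] = q
    state[1] = v
    state[2] = yo
    state[3] = vyo
    return -1


@njit(cache=True)
def volterra_recursion(Cvv, Iuv, mass, dt):
    """Forward trapezoidal solution of the first-kind Volterra equation

        int_0^t G(t-s) Cvv(s) ds = m [Cvv(0) - Cvv(t)] - int_0^t Cuv(s) ds,

    where Iuv is the trapezoidal cumulative integral of Cuv.  Returns
    (G, bad) with bad = -1 on success or the lag index where the recursion
    exceeded 1e6 times the running G scale (instability)."""
    n = Cvv.size
    G = np.zeros(n)
    c0 = Cvv[0]
    base = 0.0  # friction scale set by the first decade of lags
    for i in range(1, n):
        s = 0.0
        for j in range(1, i):
            s += G[i - j] * Cvv[j]
        G[i] = (mass * (c0 - Cvv[i]) - Iuv[i] - dt * s) / (dt * c0 / 2.0)
        a = abs(G[i])
        if not np.isfinite(G[i]):
            return G, i
        if i <= 10:
            if a > base:
                base = a
        elif a > 1e6 * (base + 1e-300):
            return G, i
    return G, -1
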