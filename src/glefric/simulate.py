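"""Synthetic GLE trajectories via Markovian embedding.

This module generates the package's synthetic study data: stationary 1D
reaction-coordinate trajectories evolving under a prescribed free-energy
profile and friction memory kernel, plus Ornstein-Uhlenbeck shear-stress
surrogates for the Green-Kubo viscosity pipeline.  See
:mod:`glefric._integrator` for the embedding and splitting scheme.
"""

from __future__ import annotations

import math

import numpy as np

from ._integrator import run_gle_chunk
from .kernels import MemoryKernel
from .potentials import POT_TABLE, FreeEnergyProfile, force_table
from .trajectory import Trajectory


class TimestepError(ValueError):
    """Timestep too coarse for the requested kernel."""


class UnstableSimulationError(RuntimeError):
    """Non-finite state encountered during integration."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite force/state at integration step {step}")


_CHUNK = 1_000_000


def simulate_gle(
    profile: FreeEnergyProfile,
    kernel: MemoryKernel,
    mass: float,
    temperature: float = 1.0,
    dt: float = 0.001,
    n_steps: int = 1_000_000,
    seed: int = 0,
    q0: float | None = None,
    equilibrate: bool = True,
    coordinate_kind: str | None = None,
) -> Trajectory:
    """Integrate the GLE with the given kernel and potential.

    Parameters
    ----------
    profile : FreeEnergyProfile
        Free-energy profile U(q) in k_BT.
    kernel : MemoryKernel
        Friction memory kernel; each exponential component is embedded as
        one overdamped auxiliary variable, the oscillating component as one
        inertial auxiliary variable.
    mass : float
        Effective reaction-coordinate mass, k_BT ps^2 / unit^2.
    temperature : float
        Thermal energy in k_BT units (1.0 in reduced units).
    dt : float
        Timestep (ps).  Must satisfy dt <= min(tau_i)/10 and
        dt <= 0.1/omega for oscillating modes; too-coarse timesteps are
        rejected rather than silently subsampled.
    n_steps : int
        Number of recorded production steps.
    seed : int
        Seed for the single-stream PCG64 generator; identical inputs and
        seed give bitwise-identical trajectories.
    q0 : float, optional
        Initial position; defaults to the profile's deepest minimum.
    equilibrate : bool
        Discard max(10 * tau_slowest, 1000 * dt) before recording.
    """
    if mass <= 0:
        raise ValueError("mass must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if n_steps < 2:
        raise ValueError("need at least 2 recorded steps")
    _validate_timestep(dt, kernel)

    rng = np.random.default_rng(seed)

    # embedding parameters -------------------------------------------------
    n_exp = len(kernel.exponentials)
    ke = np.array([c.gamma / c.tau for c in kernel.exponentials])
    ce = np.array([math.exp(-dt / c.tau) for c in kernel.exponentials])
    se = np.array(
        [
            math.sqrt(temperature / k * (1.0 - c * c)) if k > 0 else 0.0
            for k, c in zip(ke, ce)
        ]
    )
    has_osc = len(kernel.oscillations) == 1
    if has_osc:
        o = kernel.oscillations[0]
        ko = o.spring
        myo = o.gamma * o.tau / 2.0
        co = math.exp(-o.gamma * dt / myo)  # = exp(-2 dt / tau_osc)
        so = math.sqrt(temperature / myo * (1.0 - co * co))
    else:
        ko = myo = 1.0
        co = so = 0.0

    # potential dispatch ---------------------------------------------------
    code = profile._code
    p = np.asarray(profile._params, dtype=float)
    if code == POT_TABLE:
        tq, tF = force_table(profile)
        tq0, tdq = float(tq[0]), float(tq[1] - tq[0])
        tF = np.asarray(tF, dtype=float)
    else:
        tq0, tdq = 0.0, 1.0
        tF = np.zeros(2)
    periodic = bool(profile.periodic)
    period = float(profile.period) if periodic else 0.0

    # initial conditions: q at the designated minimum, auxiliaries from
    # their conditional equilibrium given q0
    if q0 is None:
        mins = profile.minima
        q0 = min(mins, key=lambda s: float(profile.energy(s.position))).position if mins else 0.0
    q0 = float(q0)
    v0 = math.sqrt(temperature / mass) * rng.standard_normal()
    ye = q0 + np.where(ke > 0, np.sqrt(temperature / np.maximum(ke, 1e-300)), 0.0) * rng.standard_normal(n_exp)
    if has_osc:
        yo = q0 + math.sqrt(temperature / ko) * rng.standard_normal()
        vyo = math.sqrt(temperature / myo) * rng.standard_normal()
    else:
        yo = vyo = 0.0

    state = np.array([q0, v0, yo, vyo], dtype=float)

    n_equil = int(max(10.0 * kernel.slowest_time / dt, 1000.0)) if equilibrate else 0
    out = np.empty(n_steps)
    empty = np.empty(0)
    done = 0
    total = n_equil + n_steps
    while done < total:
        n = min(_CHUNK, total - done)
        ne = rng.standard_normal((n, n_exp))
        no = rng.standard_normal(n) if has_osc else np.zeros(n)
        if done + n <= n_equil:
            buf = empty
        elif done >= n_equil:
            buf = out[done - n_equil : done - n_equil + n]
        else:
            # chunk straddles the equilibration boundary: split it
            n = n_equil - done
            ne = ne[:n]
            no = no[:n]
            buf = empty
        bad = run_gle_chunk(
            state, ye, mass, temperature, dt,
            ke, ce, se, has_osc, ko, myo, co, so,
            code, p, tq0, tdq, tF, periodic, period,
            ne, no, buf,
        )
        if bad >= 0:
            raise UnstableSimulationError(done + bad - n_equil)
        done += n

    kind = coordinate_kind or ("angle" if periodic else "distance")
    return Trajectory(
        values=out,
        dt=dt,
        temperature=temperature,
        periodic=periodic,
        period=profile.period,
        kind=kind,
        mass=mass,
        kernel=kernel,
        seed=seed,
        meta={"n_equil": n_equil, "profile_kind": profile.kind},
    )


def _validate_timestep(dt: float, kernel: MemoryKernel):
    if dt <= 0:
        raise TimestepError("timestep must be > 0")
    for c in kernel.exponentials:
        if dt > c.tau / 10.0:
            raise TimestepError(
                f"dt={dt} too large for exponential time scale tau={c.tau} "
                f"(need dt <= tau/10)"
            )
    for c in kernel.oscillations:
        if dt > c.tau / 10.0:
            raise TimestepError(
                f"dt={dt} too large for oscillating decay time tau={c.tau}"
            )
        if dt > 0.1 / c.omega:
            raise TimestepError(
                f"dt={dt} too large for oscillation frequency omega={c.omega} "
                f"(need dt <= 0.1/omega)"
            )


def generate_stress_series(
    model: str = "ou_process",
    sigma2: float = 1.0,
    tau_c: float = 0.5,
    dt: float = 0.01,
    n_steps: int = 100_000,
    seed: int = 0,
    n_components: int = 1,
):
    """Stationary Gaussian shear-stress surrogate with exponential
    autocorrelation sigma2 * exp(-t/tau_c) (exact integral sigma2 * tau_c).

    Returns an array of shape (n_steps,) or (n_steps, n_components).
    """
    if model != "ou_process":
        raise ValueError(f"unknown stress model: {model!r}")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if tau_c <= 0 or dt <= 0 or n_steps < 1:
        raise ValueError("need tau_c > 0, dt > 0, n_steps >= 1")

    rng = np.random.default_rng(seed)
    if sigma2 == 0.0:
        shape = (n_steps,) if n_components == 1 else (n_steps, n_components)
        return np.zeros(shape)

    from scipy.signal import lfilter

    c = math.exp(-dt / tau_c)
    s = math.sqrt(sigma2 * (1.0 - c * c))
    cols = []
    for _ in range(n_components):
        x0 = math.sqrt(sigma2) * rng.standard_normal()
        noise = s * rng.standard_normal(n_steps)
        noise[0] = x0  # exact stationary start
        x = lfilter([1.0], [1.0, -c], noise)
        cols.append(x)
    out = np.column_stack(cols)
    return out[:, 0] if n_components == 1 else out
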