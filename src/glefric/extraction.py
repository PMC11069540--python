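"""Friction memory-kernel extraction from reaction-coordinate trajectories.

Given a stationary trajectory q(t), a free-energy profile U(q) and an
effective mass m, the running friction integral G(t) = int_0^t Gamma is
obtained by solving the first-kind Volterra equation that follows from
multiplying the GLE by v(0), averaging, and integrating once in time:

    int_0^t G(t-s) C_vv(s) ds = m [C_vv(0) - C_vv(t)] - int_0^t C_{dU,v}(s) ds

with C_vv(t) = <v(t) v(0)> and C_{dU,v}(t) = <dU/dq(q(t)) v(0)>.  The
equation is discretized with the trapezoidal rule and solved by forward
recursion; the kernel Gamma(t) follows by Savitzky-Golay differentiation
of G(t), and the total friction gamma = G(t -> inf) from the plateau of G.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.signal import savgol_filter

from ._integrator import volterra_recursion
from .potentials import FreeEnergyProfile
from .trajectory import Trajectory
from .units import minimum_image


class ExtractionInstabilityError(RuntimeError):
    def __init__(self, lag: int):
        self.lag = lag
        super().__init__(
            f"Volterra recursion unstable: |G| blew up at lag index {lag}"
        )


class NoPlateauError(RuntimeError):
    """G(t) has no plateau inside the computed lag window."""


# ----------------------------------------------------------------------


def compute_velocity(traj: Trajectory) -> np.ndarray:
    """Central-difference velocity v_k = (q_{k+1} - q_{k-1}) / (2 dt).

    For periodic (angle) coordinates the difference is accumulated from
    the two single-step minimum-image increments, so a wrap from +179 deg
    to -179 deg counts as a 2 deg displacement.  Output has length
    len(traj) - 2 and is aligned with samples 1 .. n-2.
    """
    q = traj.values
    if q.size < 3:
        raise ValueError("need at least 3 samples for a central difference")
    steps = np.diff(q)
    if traj.periodic:
        steps = minimum_image(steps, traj.period)
    return (steps[1:] + steps[:-1]) / (2.0 * traj.dt)


@dataclass
class CorrelationSet:
    """Stationary correlation functions on the lag grid t_i = i * dt."""

    dt: float
    Cvv: np.ndarray          # <v(t_i) v(0)>
    Cuv: np.ndarray          # <dU/dq(q(t_i)) v(0)>
    counts: np.ndarray       # samples per lag
    block_Cvv: np.ndarray | None = None   # (n_blocks, n_lag)
    block_Cuv: np.ndarray | None = None

    def __post_init__(self):
        if self.Cvv[0] <= 0:
            raise ValueError("C_vv(0) must be > 0")


def _corr_sums(a: np.ndarray, b: np.ndarray, max_lag: int):
    """sum_t a[t+k] b[t] for k = 0..max_lag via FFT."""
    n = a.size
    nfft = next_fast_len(n + max_lag + 1)
    fa = rfft(a, nfft)
    fb = rfft(b, nfft)
    s = irfft(fa * np.conj(fb), nfft)
    return s[: max_lag + 1]


def compute_correlations(
    traj: Trajectory,
    profile: FreeEnergyProfile,
    max_lag: int | None = None,
    n_blocks: int = 10,
) -> CorrelationSet:
    """Estimate C_vv and C_{dU,v} using all admissible time origins.

    The series is split into ``n_blocks`` contiguous blocks; correlations
    are accumulated within blocks (block estimates are retained for the
    plateau-friction standard error).  ``max_lag`` defaults to 1% of the
    trajectory duration and may not exceed it.
    """
    v = compute_velocity(traj)
    q = traj.values[1:-1]
    gradu = np.asarray(profile.grad(q), dtype=float)
    n = v.size

    if max_lag is None:
        max_lag = max(int(0.01 * n), 10)
    if max_lag >= n // max(n_blocks, 1) // 2:
        raise ValueError(
            f"max_lag={max_lag} too large for {n} velocity samples "
            f"in {n_blocks} blocks (need max_lag < n/(2*n_blocks))"
        )

    qmin, qmax = q.min(), q.max()
    if not profile.periodic and (qmin < profile.q[0] or qmax > profile.q[-1]):
        raise ValueError(
            f"profile grid [{profile.q[0]:g}, {profile.q[-1]:g}] does not "
            f"cover the sampled range [{qmin:g}, {qmax:g}]"
        )

    v = v - v.mean()
    gradu = gradu - gradu.mean()

    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    svv = np.zeros(max_lag + 1)
    suv = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    bvv = np.zeros((n_blocks, max_lag + 1))
    buv = np.zeros((n_blocks, max_lag + 1))
    for b in range(n_blocks):
        vb = v[edges[b] : edges[b + 1]]
        ub = gradu[edges[b] : edges[b + 1]]
        nb = vb.size
        cts = nb - np.arange(max_lag + 1)
        sv = _corr_sums(vb, vb, max_lag)
        su = _corr_sums(ub, vb, max_lag)
        svv += sv
        suv += su
        counts += cts
        bvv[b] = sv / cts
        buv[b] = su / cts

    return CorrelationSet(
        dt=traj.dt,
        Cvv=svv / counts,
        Cuv=suv / counts,
        counts=counts,
        block_Cvv=bvv,
        block_Cuv=buv,
    )


def average_correlations(corrs: list) -> CorrelationSet:
    """Pool correlation estimates from replicate trajectories.

    Lag grids must match; estimates are combined weighted by their sample
    counts, and the per-replicate block estimates are concatenated so the
    pooled plateau stderr reflects all replicates.
    """
    if not corrs:
        raise ValueError("no correlation sets to average")
    dt = corrs[0].dt
    n = corrs[0].Cvv.size
    for c in corrs[1:]:
        if c.Cvv.size != n or abs(c.dt - dt) > 1e-12 * dt:
            raise ValueError("correlation sets have mismatched lag grids")
    counts = np.sum([c.counts for c in corrs], axis=0)
    cvv = np.sum([c.Cvv * c.counts for c in corrs], axis=0) / counts
    cuv = np.sum([c.Cuv * c.counts for c in corrs], axis=0) / counts
    blocks_v = [c.block_Cvv for c in corrs if c.block_Cvv is not None]
    blocks_u = [c.block_Cuv for c in corrs if c.block_Cuv is not None]
    return CorrelationSet(
        dt=dt, Cvv=cvv, Cuv=cuv, counts=counts,
        block_Cvv=np.vstack(blocks_v) if blocks_v else None,
        block_Cuv=np.vstack(blocks_u) if blocks_u else None,
    )


# ----------------------------------------------------------------------


@dataclass
class KernelEstimate:
    """Discretized running friction integral and kernel.

    Attributes
    ----------
    t : ndarray
        Lag grid t_i = i * dt.
    G : ndarray
        Running friction integral, k_BT ps / unit^2; G[0] = 0.
    Gamma : ndarray
        Memory kernel from Savitzky-Golay differentiation of G.
    gamma : float or None
        Plateau friction (filled by :func:`plateau_friction`).
    gamma_stderr : float or None
    window : tuple or None
        Plateau window (t_a, t_b).
    """

    t: np.ndarray
    G: np.ndarray
    Gamma: np.ndarray
    mass: float
    gamma: float | None = None
    gamma_stderr: float | None = None
    window: tuple | None = None
    block_G: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def extract_G(
    corr: CorrelationSet,
    mass: float,
    dt: float | None = None,
    savgol_window: int = 5,
    with_blocks: bool = True,
) -> KernelEstimate:
    """Solve the Volterra equation for G(t) by forward recursion."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    dt = corr.dt if dt is None else dt

    G, bad = _recursion(corr.Cvv, corr.Cuv, mass, dt)
    if bad >= 0:
        raise ExtractionInstabilityError(bad)

    block_G = None
    if with_blocks and corr.block_Cvv is not None:
        blocks = []
        for cv, cu in zip(corr.block_Cvv, corr.block_Cuv):
            gb, badb = _recursion(cv, cu, mass, dt)
            if badb < 0:
                blocks.append(gb)
        if len(blocks) >= 3:
            block_G = np.array(blocks)

    t = np.arange(G.size) * dt
    w = min(savgol_window if savgol_window % 2 == 1 else savgol_window + 1, G.size - 1)
    gamma_t = savgol_filter(G, w, polyorder=min(3, w - 1), deriv=1, delta=dt)
    return KernelEstimate(
        t=t, G=G, Gamma=gamma_t, mass=mass, block_G=block_G,
        diagnostics={"n_lags": G.size, "Cvv0": float(corr.Cvv[0])},
    )


def _recursion(Cvv, Cuv, mass, dt):
    from scipy.integrate import cumulative_trapezoid

    Iuv = np.concatenate(([0.0], cumulative_trapezoid(Cuv, dx=dt)))
    return volterra_recursion(
        np.ascontiguousarray(Cvv, dtype=np.float64),
        np.ascontiguousarray(Iuv, dtype=np.float64),
        float(mass), float(dt),
    )


# ----------------------------------------------------------------------


def plateau_friction(
    est: KernelEstimate,
    tol: float = 0.01,
    min_fraction: float = 0.1,
) -> tuple[float, float, tuple]:
    """Plateau friction gamma = G(t -> inf) from the longest trailing
    window over which the total drift of G is below ``tol`` times gamma.

    The window is grown backwards from the tail; the drift criterion is
    |slope| * (t_b - t_a) < tol * gamma_win.  The plateau value is then
    the mean of G over the *trailing half* of the longest accepted window
    (the leading half may still carry the last of the rise, which would
    bias the mean low).  Standard error comes from block averages of G
    when available, else from the within-window scatter.  Raises
    :class:`NoPlateauError` when even the smallest trailing window
    (``min_fraction`` of the lag range) violates the criterion.
    """
    t, G = est.t, est.G
    n = t.size
    if n < 10:
        raise ValueError("kernel estimate too short for plateau detection")

    candidates = np.unique(
        np.geomspace(max(int(min_fraction * n), 5), n - 5, 40).astype(int)
    )[::-1]  # window lengths, longest first
    chosen = None
    for wlen in candidates:
        i0 = n - wlen
        tw, gw = t[i0:], G[i0:]
        gbar = gw.mean()
        slope = np.polyfit(tw, gw, 1)[0]
        if abs(slope) * (tw[-1] - tw[0]) < tol * abs(gbar):
            chosen = (i0, slope)
            break
    if chosen is None:
        raise NoPlateauError(
            f"no plateau: smallest trailing window still drifts by more "
            f"than {tol:.2%} of its mean (G[-1]={G[-1]:.4g})"
        )
    i0, slope = chosen
    i0 = (i0 + n) // 2  # trailing half of the accepted window
    gamma = G[i0:].mean()
    if est.block_G is not None:
        bmeans = est.block_G[:, i0:].mean(axis=1)
        stderr = float(bmeans.std(ddof=1) / math.sqrt(bmeans.size))
    else:
        stderr = float(G[i0:].std(ddof=1) / math.sqrt(max(1.0, (n - i0) / 50.0)))
    window = (float(t[i0]), float(t[-1]))
    est.gamma = float(gamma)
    est.gamma_stderr = stderr
    est.window = window
    est.diagnostics["plateau_slope"] = float(slope)
    return float(gamma), stderr, window


def extract_kernel(
    traj: Trajectory,
    profile: FreeEnergyProfile,
    mass: float | None = None,
    max_lag: int | None = None,
    tol: float = 0.01,
    n_blocks: int = 10,
) -> KernelEstimate:
    """Convenience pipeline: correlations -> Volterra -> plateau.

    ``mass=None`` estimates the effective mass by equipartition
    (:func:`glefric.profiles.estimate_mass`).
    """
    if mass is None:
        if traj.mass is not None:
            mass = traj.mass
        else:
            from .profiles import estimate_mass

            mass = estimate_mass(traj).m
    corr = compute_correlations(traj, profile, max_lag=max_lag, n_blocks=n_blocks)
    est = extract_G(corr, mass=mass)
    plateau_friction(est, tol=tol)
    return est
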