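"""Free-energy profiles and effective masses estimated from trajectories.

The free energy is obtained by Boltzmann inversion of the sampled density,
U(q) = -k_BT log rho(q), on a (periodic, for angles) histogram, smoothed
through a cubic spline fitted to the log-density.  The effective mass
comes from equipartition, m = k_BT / <v^2>, with a Richardson
extrapolation in the timestep to remove the O(dt^2) bias of the
central-difference velocity (on an underdamped harmonic reference the
discrete estimator satisfies <v_hat^2> = <v^2> sinc^2(w dt), so the bias
is quadratic in dt and two spacings suffice to cancel it).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .extraction import compute_velocity
from .potentials import FreeEnergyProfile, StationaryPoint
from .trajectory import Trajectory
from .units import minimum_image


class UnsampledRegionError(ValueError):
    """Interior histogram bins without counts (barrier too high for run length)."""


def _n_bins_scott(x: np.ndarray) -> int:
    h = 3.49 * x.std(ddof=1) / x.size ** (1.0 / 3.0)
    span = x.max() - x.min()
    return max(int(np.ceil(span / max(h, 1e-12))), 10)


def estimate_free_energy(
    traj: Trajectory,
    n_bins: int | None = None,
    smoothing: float = 2.0,
    min_counts: int = 10,
) -> FreeEnergyProfile:
    """Boltzmann inversion U = -k_BT log rho of the sampled density.

    Parameters
    ----------
    n_bins : int, optional
        Defaults to 360 bins per period for angles, Scott's rule for
        distances.
    smoothing : float
        Gaussian pre-smoothing of the histogram counts, in bins
        (periodic wrap for angles).  0 disables smoothing.
    min_counts : int
        Minimum (smoothed) counts per supported bin.
    """
    q = traj.values
    if traj.periodic:
        n_bins = n_bins or 360
        lo = -traj.period / 2.0
        hi = traj.period / 2.0
    else:
        n_bins = n_bins or _n_bins_scott(q)
        lo, hi = q.min(), q.max()
    counts, edges = np.histogram(q, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    sm = counts.astype(float)
    if smoothing > 0:
        sm = gaussian_filter1d(
            sm, smoothing, mode="wrap" if traj.periodic else "nearest"
        )

    good = np.nonzero(sm >= min_counts)[0]
    if good.size < 4:
        raise UnsampledRegionError(
            f"fewer than 4 bins reach {min_counts} counts; trajectory too short"
        )
    if traj.periodic:
        support = np.ones(n_bins, dtype=bool)
        inner_low = sm < min_counts
    else:
        # trim poorly sampled outer bins; low-count bins *between* well
        # sampled regions indicate an uncrossed barrier and are an error
        support = np.zeros(n_bins, dtype=bool)
        support[good[0] : good[-1] + 1] = True
        inner_low = support & (sm < min_counts)
    if np.any(inner_low):
        bad = centers[inner_low]
        raise UnsampledRegionError(
            f"{bad.size} interior bins have fewer than {min_counts} counts "
            f"(gaps near q={bad[:5]}); the trajectory does not sample "
            f"across the barrier"
        )

    rho = sm[support] / (sm.sum() * width)
    u = -traj.temperature * np.log(rho)
    u -= u.min()

    prof = FreeEnergyProfile(
        q=centers[support],
        u=u,
        periodic=traj.periodic,
        period=traj.period if traj.periodic else None,
        provenance="estimated",
        kind="estimated",
    )
    prof.stationary_points = _refine_stationary_points(prof)
    return prof


def _refine_stationary_points(
    prof: FreeEnergyProfile, du_window: float = 0.5
) -> list[StationaryPoint]:
    """Stationary points of an estimated (noisy) profile.

    Locations come from the spline; curvatures from a local quadratic
    least-squares fit over the surrounding window where |U - U0| <=
    ``du_window`` k_BT, which is far more noise-tolerant than the spline's
    pointwise second derivative.  Points whose local fit contradicts their
    min/max classification (spline wiggles) are dropped.
    """
    raw = prof.locate_stationary_points()
    q, u = prof.q, prof.u
    period = prof.period if prof.periodic else None
    out: list[StationaryPoint] = []
    for s in raw:
        if period is not None:
            dq = minimum_image(q - s.position, period)
        else:
            dq = q - s.position
        u0 = float(prof.energy(s.position))
        sel = np.abs(u - u0) <= du_window
        # restrict to the contiguous window containing the point
        order = np.argsort(dq)
        dqo, uo, selo = dq[order], u[order], sel[order]
        i0 = int(np.argmin(np.abs(dqo)))
        lo = i0
        while lo > 0 and selo[lo - 1]:
            lo -= 1
        hi = i0
        while hi < dqo.size - 1 and selo[hi + 1]:
            hi += 1
        if hi - lo + 1 < 5:
            out.append(s)
            continue
        a, b, _ = np.polyfit(dqo[lo : hi + 1], uo[lo : hi + 1], 2)
        curv = 2.0 * a
        if (s.kind == "min" and curv <= 0) or (s.kind == "max" and curv >= 0):
            continue  # spurious wiggle
        # refine the position from the quadratic vertex when it stays local
        shift = -b / (2.0 * a)
        pos = s.position + shift if abs(shift) < (dqo[hi] - dqo[lo]) / 2 else s.position
        if period is not None:
            pos = float(minimum_image(pos, period)) if abs(pos) > period / 2 else pos
        out.append(StationaryPoint(float(pos), s.kind, float(curv)))
    return out


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class EffectiveMass:
    m: float
    stderr: float
    estimator: str = "equipartition"

    def __post_init__(self):
        if self.m <= 0:
            raise ValueError("effective mass must be > 0")


def estimate_mass(traj: Trajectory, n_blocks: int = 10) -> EffectiveMass:
    """Equipartition mass m = k_BT / <v^2> with central-difference bias
    correction by Richardson extrapolation over spacings dt and 2 dt."""
    v1 = compute_velocity(traj)
    if np.allclose(v1, 0.0):
        raise ValueError("degenerate series: zero velocity variance")

    # resolution warning: velocity autocorrelation must be resolved
    c0 = float(np.mean(v1 * v1))
    c1 = float(np.mean(v1[1:] * v1[:-1]))
    if c1 / c0 < 0.5:
        warnings.warn(
            f"velocity autocorrelation C(dt)/C(0) = {c1 / c0:.2f} < 0.5: "
            "the timestep under-resolves the velocity; the mass estimate "
            "is biased",
            RuntimeWarning,
            stacklevel=2,
        )

    steps = np.diff(traj.values)
    if traj.periodic:
        steps = minimum_image(steps, traj.period)
    v2 = (steps[:-3] + steps[1:-2] + steps[2:-1] + steps[3:]) / (4.0 * traj.dt)

    m1 = float(np.mean(v1 * v1))
    m2 = float(np.mean(v2 * v2))
    v2_extrap = (4.0 * m1 - m2) / 3.0
    if v2_extrap <= 0:
        v2_extrap = m1  # fall back to the raw estimator

    mass = traj.temperature / v2_extrap

    # block stderr on the raw <v^2>, propagated to the mass
    edges = np.linspace(0, v1.size, n_blocks + 1).astype(int)
    bm = np.array([np.mean(v1[a:b] ** 2) for a, b in zip(edges[:-1], edges[1:])])
    rel = bm.std(ddof=1) / math.sqrt(n_blocks) / bm.mean()
    return EffectiveMass(m=mass, stderr=mass * rel)


# ----------------------------------------------------------------------


def barrier_descriptor(
    profile: FreeEnergyProfile,
    from_min: float,
    to_min: float,
) -> tuple[float, float, float, float]:
    """Barrier inputs for rate theory between two minima.

    Returns (U0, U''_min, U''_max, L): barrier height from the ``from``
    minimum to the intervening maximum, curvature at the ``from`` minimum,
    curvature at the barrier top, and L = |q_barrier - q_from| (minimum
    image for periodic profiles).  All outputs are invariant under adding
    a constant to the profile.
    """
    mins = profile.minima
    maxs = profile.maxima
    if not mins or not maxs:
        raise ValueError("profile has no barrier (needs minima and a maximum)")

    src = _nearest(mins, from_min, profile)
    dst = _nearest(mins, to_min, profile)
    if math.isclose(src.position, dst.position, abs_tol=1e-9):
        raise ValueError("from_min and to_min resolve to the same minimum")

    # intervening maximum on the path src -> dst (shortest arc if periodic)
    a, b = src.position, dst.position
    if profile.periodic:
        d = minimum_image(b - a, profile.period)
        between = [
            s for s in maxs
            if 0.0 < float(minimum_image(s.position - a, profile.period)) / d < 1.0
            and abs(minimum_image(s.position - a, profile.period)) < abs(d)
        ]
    else:
        lo, hi = sorted((a, b))
        between = [s for s in maxs if lo < s.position < hi]
    if not between:
        raise ValueError(
            f"no barrier between minima at {a:g} and {b:g}"
        )
    top = min(
        between,
        key=lambda s: abs(
            minimum_image(s.position - a, profile.period) if profile.periodic
            else s.position - a
        ),
    )
    u0 = float(profile.energy(top.position) - profile.energy(src.position))
    L = (
        abs(float(minimum_image(top.position - a, profile.period)))
        if profile.periodic
        else abs(top.position - a)
    )
    return u0, src.curvature, top.curvature, L


def _nearest(points: list[StationaryPoint], x: float, profile: FreeEnergyProfile):
    if profile.periodic:
        return min(points, key=lambda s: abs(float(minimum_image(s.position - x, profile.period))))
    return min(points, key=lambda s: abs(s.position - x))
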