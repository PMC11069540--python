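"""Free-energy profiles U(q) for 1D reaction coordinates.

A :class:`FreeEnergyProfile` couples a gridded representation (used for
plotting and I/O) with a smooth interpolant or analytic closed form (used
for forces, curvatures and quadrature).  Energies are in units of k_B*T,
coordinates in rad (dihedral angles, periodic) or nm (distances).

The analytic factory :func:`make_potential` provides the standard fixtures:
a harmonic well, a quartic double well, a flat profile, a three-minimum
cosine dihedral profile mimicking an alkane trans/gauche landscape, and
tabulated profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, minimize_scalar

from .units import RAD_PER_DEG

TWO_PI = 2.0 * math.pi

# integer codes used by the numba integrator to dispatch on potential kind
POT_FLAT = 0
POT_HARMONIC = 1
POT_QUARTIC = 2
POT_COSINE = 3
POT_TABLE = 4


@dataclass(frozen=True)
class StationaryPoint:
    position: float
    kind: str  # "min" | "max"
    curvature: float  # U'' in k_BT / unit**2

    def __post_init__(self):
        if self.kind not in ("min", "max"):
            raise ValueError(f"stationary point kind must be min|max, got {self.kind}")


@dataclass
class FreeEnergyProfile:
    """Gridded free-energy profile with smooth derivatives.

    Attributes
    ----------
    q, u : ndarray
        Strictly increasing grid and U(q) in k_BT.
    periodic : bool
        Periodic coordinate (dihedral angle).
    period : float or None
        Period (2*pi for dihedrals in rad).
    provenance : str
        "analytic" or "estimated".
    stationary_points : list of StationaryPoint
    barrier : float or None
        Barrier height U0 (k_BT) between the designated minimum and the
        adjacent maximum, if defined.
    """

    q: np.ndarray
    u: np.ndarray
    periodic: bool = False
    period: float | None = None
    provenance: str = "analytic"
    stationary_points: list[StationaryPoint] = field(default_factory=list)
    barrier: float | None = None
    kind: str = "tabulated"
    # analytic closed forms (optional); fall back to the spline when absent
    _u_fn: object | None = None
    _du_fn: object | None = None
    _d2u_fn: object | None = None
    # numba dispatch
    _code: int = POT_TABLE
    _params: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.q.ndim != 1 or self.q.size < 4:
            raise ValueError("profile grid must be 1D with >= 4 points")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("profile grid must be strictly increasing")
        if self.q.shape != self.u.shape:
            raise ValueError("q and u must have identical shapes")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("profile values must be finite")
        if self.periodic and not self.period:
            raise ValueError("periodic profile requires a period")
        self._spline = self._build_spline()

    def _build_spline(self) -> CubicSpline:
        if self.periodic:
            # close the period so the spline is C2-periodic on [q0, q0+P]
            q = self.q
            u = self.u
            if not math.isclose(q[-1] - q[0], self.period, rel_tol=1e-9):
                q = np.append(q, q[0] + self.period)
                u = np.append(u, u[0])
            else:
                u = u.copy()
                u[-1] = u[0]
            return CubicSpline(q, u, bc_type="periodic")
        return CubicSpline(self.q, self.u)

    # ------------------------------------------------------------------
    def _map_in(self, x):
        x = np.asarray(x, dtype=float)
        if self.periodic:
            q0 = self.q[0]
            return (x - q0) % self.period + q0
        return x

    def energy(self, x):
        """U(x) in k_BT."""
        if self._u_fn is not None:
            return self._u_fn(np.asarray(x, dtype=float))
        return self._spline(self._map_in(x))

    def grad(self, x):
        """dU/dx (the mean force is the negative of this)."""
        if self._du_fn is not None:
            return self._du_fn(np.asarray(x, dtype=float))
        return self._spline(self._map_in(x), 1)

    def curvature(self, x):
        """U''(x)."""
        if self._d2u_fn is not None:
            return self._d2u_fn(np.asarray(x, dtype=float))
        return self._spline(self._map_in(x), 2)

    __call__ = energy

    # ------------------------------------------------------------------
    @property
    def minima(self) -> list[StationaryPoint]:
        return [s for s in self.stationary_points if s.kind == "min"]

    @property
    def maxima(self) -> list[StationaryPoint]:
        return [s for s in self.stationary_points if s.kind == "max"]

    def locate_stationary_points(self) -> list[StationaryPoint]:
        """(Re)locate stationary points from the smooth interpolant."""
        pts: list[StationaryPoint] = []
        der = self._spline.derivative()
        roots = der.roots(extrapolate=False)
        roots = np.unique(np.round(np.real(roots), 12))
        if self.periodic:
            q0 = self.q[0]
            roots = np.unique(np.round((roots - q0) % self.period + q0, 10))
        for r in roots:
            c = float(self.curvature(r))
            if abs(c) < 1e-12:
                continue  # inflection / flat
            pts.append(StationaryPoint(float(r), "min" if c > 0 else "max", c))
        pts.sort(key=lambda s: s.position)
        return pts

    def validate(self, atol: float = 1e-8):
        """Check the documented structural invariants."""
        if self.periodic:
            u0 = float(self.energy(self.q[0]))
            u1 = float(self.energy(self.q[0] + self.period))
            if abs(u0 - u1) > 1e-6 * max(1.0, abs(u0)) + atol:
                raise ValueError("periodic profile does not match at the boundary")
        for s in self.stationary_points:
            if s.kind == "min" and s.curvature <= 0:
                raise ValueError(f"minimum at {s.position} has curvature <= 0")
            if s.kind == "max" and s.curvature >= 0:
                raise ValueError(f"maximum at {s.position} has curvature >= 0")
        if self.barrier is not None and self.barrier < 0:
            raise ValueError("barrier height must be >= 0")
        return self


# ----------------------------------------------------------------------
# analytic factory


def _grid(periodic: bool, period: float | None, lo: float, hi: float, n: int = 721):
    if periodic:
        return np.linspace(-period / 2.0, period / 2.0, n, endpoint=False) + 0.0
    return np.linspace(lo, hi, n)


def make_potential(kind: str, **params) -> FreeEnergyProfile:
    """Construct an analytic free-energy profile.

    Parameters
    ----------
    kind : {"flat", "harmonic", "double_well_quartic", "cosine_dihedral", "tabulated"}
    params :
        flat: ``extent`` (half-width, default 10).
        harmonic: ``k`` (curvature, k_BT/unit^2), ``q0`` (minimum, default 0).
        double_well_quartic: ``barrier`` U0 (k_BT), ``half_separation`` L
            (minima at +-L); U(q) = U0*((q/L)^2 - 1)^2.
        cosine_dihedral: ``barrier`` U0 = trans->gauche barrier (k_BT),
            ``gauche_offset`` dU = U(gauche) - U(trans) >= 0 (default 0);
            trans minimum at 0 rad, gauche minima at +-120 deg.
        tabulated: ``q``, ``u`` arrays plus ``periodic``/``period``.
    """
    if kind == "flat":
        extent = float(params.pop("extent", 10.0))
        _reject_unknown(params)
        q = _grid(False, None, -extent, extent)
        zero = lambda x: np.zeros_like(np.asarray(x, dtype=float))
        return FreeEnergyProfile(
            q=q, u=np.zeros_like(q), kind="flat",
            _u_fn=zero, _du_fn=zero, _d2u_fn=zero,
            _code=POT_FLAT, _params=np.zeros(4),
        )

    if kind == "harmonic":
        k = float(params.pop("k"))
        q0 = float(params.pop("q0", 0.0))
        extent = float(params.pop("extent", 6.0 / math.sqrt(max(k, 1e-12))))
        _reject_unknown(params)
        if k <= 0:
            raise ValueError("harmonic curvature k must be > 0")
        q = _grid(False, None, q0 - extent, q0 + extent)
        u_fn = lambda x: 0.5 * k * (x - q0) ** 2
        du_fn = lambda x: k * (x - q0)
        d2u_fn = lambda x: np.full_like(np.asarray(x, dtype=float), k)
        return FreeEnergyProfile(
            q=q, u=u_fn(q), kind="harmonic",
            stationary_points=[StationaryPoint(q0, "min", k)],
            barrier=None,
            _u_fn=u_fn, _du_fn=du_fn, _d2u_fn=d2u_fn,
            _code=POT_HARMONIC, _params=np.array([k, q0, 0.0, 0.0]),
        )

    if kind == "double_well_quartic":
        u0 = float(params.pop("barrier"))
        L = float(params.pop("half_separation", 1.0))
        _reject_unknown(params)
        if u0 <= 0 or L <= 0:
            raise ValueError("quartic double well needs barrier > 0 and L > 0")
        q = _grid(False, None, -2.5 * L, 2.5 * L)
        u_fn = lambda x: u0 * ((np.asarray(x, dtype=float) / L) ** 2 - 1.0) ** 2
        du_fn = lambda x: 4.0 * u0 * np.asarray(x, dtype=float) * ((np.asarray(x, dtype=float) / L) ** 2 - 1.0) / L**2
        d2u_fn = lambda x: (4.0 * u0 / L**2) * (3.0 * (np.asarray(x, dtype=float) / L) ** 2 - 1.0)
        pts = [
            StationaryPoint(-L, "min", 8.0 * u0 / L**2),
            StationaryPoint(0.0, "max", -4.0 * u0 / L**2),
            StationaryPoint(L, "min", 8.0 * u0 / L**2),
        ]
        return FreeEnergyProfile(
            q=q, u=u_fn(q), kind="double_well_quartic",
            stationary_points=pts, barrier=u0,
            _u_fn=u_fn, _du_fn=du_fn, _d2u_fn=d2u_fn,
            _code=POT_QUARTIC, _params=np.array([u0, L, 0.0, 0.0]),
        )

    if kind == "cosine_dihedral":
        u0 = float(params.pop("barrier"))
        du = float(params.pop("gauche_offset", 0.0))
        _reject_unknown(params)
        if u0 <= 0:
            raise ValueError("dihedral barrier must be > 0")
        if du < 0 or u0 <= 0.6 * du:
            raise ValueError("need gauche_offset >= 0 and barrier > 0.6*gauche_offset")
        return _cosine_dihedral(u0, du)

    if kind == "tabulated":
        q = np.asarray(params.pop("q"), dtype=float)
        u = np.asarray(params.pop("u"), dtype=float)
        periodic = bool(params.pop("periodic", False))
        period = params.pop("period", TWO_PI if periodic else None)
        _reject_unknown(params)
        prof = FreeEnergyProfile(
            q=q, u=u, periodic=periodic, period=period,
            kind="tabulated", _code=POT_TABLE,
        )
        prof.stationary_points = prof.locate_stationary_points()
        return prof

    raise ValueError(f"unknown potential kind: {kind!r}")


def _reject_unknown(params: dict):
    if params:
        raise TypeError(f"unknown potential parameters: {sorted(params)}")


def _cosine_dihedral(u0: float, du: float) -> FreeEnergyProfile:
    """Three-minimum periodic profile: trans at 0, gauche at +-120 deg.

    For du == 0 the profile is the three-fold symmetric
    U = (U0/2)(1 - cos 3q) with maxima exactly at +-60 deg and 180 deg.
    For du > 0 a cos(q) + cos(2q)/2 term (which keeps 0 and +-120 deg
    exactly stationary) raises the gauche wells by du, and the cos(3q)
    amplitude is solved so the realized trans->gauche barrier equals U0.
    """
    if du == 0.0:
        a1, a3, c = 0.0, -u0 / 2.0, u0 / 2.0
    else:
        a1 = -du / 2.25

        def realized_barrier(a3):
            res = minimize_scalar(
                lambda th: -(_cos_u(th, a1, a3)),
                bounds=(1e-3, TWO_PI / 3.0 - 1e-3), method="bounded",
                options={"xatol": 1e-12},
            )
            return -res.fun - _cos_u(0.0, a1, a3)

        lo, hi = -8.0 * (u0 + du), -1e-9
        if realized_barrier(hi) >= u0:
            raise ValueError("gauche_offset alone exceeds the requested barrier")
        a3 = brentq(lambda a: realized_barrier(a) - u0, lo, hi, xtol=1e-13)
        c = -_cos_u(0.0, a1, a3)

    def u_fn(x):
        return _cos_u(np.asarray(x, dtype=float), a1, a3) + c

    def du_fn(x):
        x = np.asarray(x, dtype=float)
        return -a1 * np.sin(x) - a1 * np.sin(2.0 * x) - 3.0 * a3 * np.sin(3.0 * x)

    def d2u_fn(x):
        x = np.asarray(x, dtype=float)
        return -a1 * np.cos(x) - 2.0 * a1 * np.cos(2.0 * x) - 9.0 * a3 * np.cos(3.0 * x)

    g = TWO_PI / 3.0  # 120 deg
    pts = [StationaryPoint(p, "min", float(d2u_fn(p))) for p in (-g, 0.0, g)]
    # maxima: symmetric pair in (0, 120deg) and the cis maximum at 180 deg
    if du == 0.0:
        tops = [math.pi / 3.0, math.pi]
    else:
        tops = []
        for a, b in ((1e-6, g - 1e-6), (g + 1e-6, math.pi - 1e-6)):
            try:
                tops.append(brentq(lambda t: float(du_fn(t)), a, b, xtol=1e-13))
            except ValueError:
                pass
        if abs(float(du_fn(math.pi))) < 1e-10 and float(d2u_fn(math.pi)) < 0:
            tops.append(math.pi)
    for t in tops:
        pts.append(StationaryPoint(t, "max", float(d2u_fn(t))))
        if t < math.pi - 1e-9:
            pts.append(StationaryPoint(-t, "max", float(d2u_fn(t))))
    pts.sort(key=lambda s: s.position)

    q = _grid(True, TWO_PI, 0, 0)
    prof = FreeEnergyProfile(
        q=q, u=u_fn(q), periodic=True, period=TWO_PI,
        kind="cosine_dihedral", stationary_points=pts, barrier=u0,
        _u_fn=u_fn, _du_fn=du_fn, _d2u_fn=d2u_fn,
        _code=POT_COSINE, _params=np.array([a1, a1 / 2.0, a3, c]),
    )
    return prof.validate()


def _cos_u(x, a1, a3):
    x = np.asarray(x, dtype=float)
    return a1 * (np.cos(x) + 0.5 * np.cos(2.0 * x)) + a3 * np.cos(3.0 * x)


def force_table(profile: FreeEnergyProfile, n: int = 4096):
    """Dense (q, -dU/dq) table for the integrator's linear interpolation."""
    if profile.periodic:
        q = np.linspace(profile.q[0], profile.q[0] + profile.period, n, endpoint=False)
    else:
        q = np.linspace(profile.q[0], profile.q[-1], n)
    return q, -profile.grad(q)
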