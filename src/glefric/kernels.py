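"""Parametric friction memory kernels.

The kernel model is a sum of up to three exponentially decaying modes and
up to one damped-oscillating mode,

    Gamma(t) = sum_i (gamma_i / tau_i) exp(-t/tau_i)
             + (1 + w^2 s^2) g / (2 s) * exp(-t/s) * [cos(w t) + sin(w t)/(w s)],

with s = tau_osc and w the angular frequency.  The normalisation is chosen
so that each amplitude equals the time integral of its component, hence the
total friction is exactly

    gamma = sum_i gamma_i^exp + gamma_1^osc = G(t -> inf),

where G(t) = int_0^t Gamma(t') dt' is the running friction integral.  The
oscillating component is exactly the kernel obtained by eliminating a
damped inertial auxiliary oscillator, which is how the simulator realises
it (see :mod:`glefric.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ExpComponent:
    """Exponential mode: amplitude gamma (k_BT ps / unit^2), time scale tau (ps)."""

    gamma: float
    tau: float

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("exponential amplitude must be >= 0")
        if self.tau <= 0:
            raise ValueError("exponential time scale must be > 0")


@dataclass(frozen=True)
class OscComponent:
    """Damped-oscillating mode: amplitude gamma, decay time tau, frequency omega."""

    gamma: float
    tau: float
    omega: float

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("oscillating amplitude must be >= 0")
        if self.tau <= 0 or self.omega <= 0:
            raise ValueError("oscillating mode needs tau > 0 and omega > 0")

    @property
    def spring(self) -> float:
        """Coupling constant k of the equivalent auxiliary oscillator."""
        return self.gamma * (1.0 + (self.omega * self.tau) ** 2) / (2.0 * self.tau)


@dataclass(frozen=True)
class MemoryKernel:
    exponentials: tuple[ExpComponent, ...] = ()
    oscillations: tuple[OscComponent, ...] = ()

    def __post_init__(self):
        if len(self.exponentials) > 3:
            raise ValueError("at most three exponential components")
        if len(self.oscillations) > 1:
            raise ValueError("at most one oscillating component")
        object.__setattr__(self, "exponentials", tuple(self.exponentials))
        object.__setattr__(self, "oscillations", tuple(self.oscillations))

    # ------------------------------------------------------------------
    @classmethod
    def from_components(cls, exp=(), osc=()) -> "MemoryKernel":
        """Build from (gamma, tau) pairs and (gamma, tau, omega) triples."""
        return cls(
            exponentials=tuple(ExpComponent(*e) for e in exp),
            oscillations=tuple(OscComponent(*o) for o in osc),
        )

    @classmethod
    def single_exponential(cls, gamma: float, tau: float) -> "MemoryKernel":
        return cls(exponentials=(ExpComponent(gamma, tau),))

    # ------------------------------------------------------------------
    @property
    def total_friction(self) -> float:
        """gamma = sum of all component amplitudes (exact by construction)."""
        return sum(c.gamma for c in self.exponentials) + sum(
            c.gamma for c in self.oscillations
        )

    @property
    def time_scales(self) -> np.ndarray:
        return np.array([c.tau for c in self.exponentials] + [c.tau for c in self.oscillations])

    @property
    def slowest_time(self) -> float:
        ts = self.time_scales
        return float(ts.max()) if ts.size else 0.0

    @property
    def fastest_time(self) -> float:
        ts = self.time_scales
        return float(ts.min()) if ts.size else 0.0

    # ------------------------------------------------------------------
    def gamma_of_t(self, t):
        """Memory kernel Gamma(t), k_BT / unit^2 / ps ... (k_BT ps / unit^2 per ps)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c in self.exponentials:
            out = out + (c.gamma / c.tau) * np.exp(-t / c.tau)
        for c in self.oscillations:
            ws = c.omega * c.tau
            out = out + (
                (1.0 + ws**2) * c.gamma / (2.0 * c.tau)
                * np.exp(-t / c.tau)
                * (np.cos(c.omega * t) + np.sin(c.omega * t) / ws)
            )
        return out

    def G_of_t(self, t):
        """Running integral G(t) = int_0^t Gamma, closed form."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c in self.exponentials:
            out = out + c.gamma * (1.0 - np.exp(-t / c.tau))
        for c in self.oscillations:
            a = 1.0 / c.tau
            w = c.omega
            k = c.spring
            e = np.exp(-a * t)
            ic = (a + e * (w * np.sin(w * t) - a * np.cos(w * t))) / (a**2 + w**2)
            is_ = (w - e * (w * np.cos(w * t) + a * np.sin(w * t))) / (a**2 + w**2)
            out = out + k * (ic + is_ / (w * c.tau))
        return out

    def laplace(self, lam, method: str = "analytic"):
        """One-sided Laplace transform K(lambda) = int_0^inf e^{-lam t} Gamma(t) dt.

        ``method="analytic"`` uses closed forms for all components;
        ``method="quadrature"`` integrates numerically (adaptive, 1e-10),
        kept as an independent cross-check route.
        """
        lam = float(lam)
        if lam < 0:
            raise ValueError("laplace variable must be >= 0")
        if method == "quadrature":
            from scipy.integrate import quad

            upper = 200.0 * max(self.slowest_time, 1e-12)
            val, _ = quad(
                lambda t: np.exp(-lam * t) * float(self.gamma_of_t(t)),
                0.0, upper, epsabs=1e-10, epsrel=1e-10, limit=500,
            )
            return val
        out = 0.0
        for c in self.exponentials:
            out += c.gamma / (1.0 + lam * c.tau)
        for c in self.oscillations:
            a = 1.0 / c.tau
            out += c.spring * (lam + 2.0 * a) / ((lam + a) ** 2 + c.omega**2)
        return out

    # ------------------------------------------------------------------
    def describe(self) -> dict:
        return {
            "exponentials": [{"gamma": c.gamma, "tau": c.tau} for c in self.exponentials],
            "oscillations": [
                {"gamma": c.gamma, "tau": c.tau, "omega": c.omega}
                for c in self.oscillations
            ],
            "total_friction": self.total_friction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MemoryKernel":
        return cls.from_components(
            exp=[(e["gamma"], e["tau"]) for e in d.get("exponentials", [])],
            osc=[(o["gamma"], o["tau"], o["omega"]) for o in d.get("oscillations", [])],
        )
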