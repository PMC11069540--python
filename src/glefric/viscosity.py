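"""Solvent-viscosity utilities.

Three routes to a solvent viscosity are provided: the Green-Kubo
estimator from equilibrium shear-stress autocorrelations,

    eta = (V / k_BT) * int_0^tc <P_ab(0) P_ab(t)> dt,

the super-heavy-water mass-scaling rule eta/eta0 = sqrt(m/m0) (an
idealized viscogen: scaling the solvent-molecule mass leaves equilibrium
structure untouched and slows all dynamics diffusively), and the Cheng
empirical correlation for water-glycerol mixtures (coefficients vendored
in ``data/cheng2008.json``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .extraction import NoPlateauError
from .simulate import generate_stress_series  # noqa: F401  (fixture generator lives with the simulator)


@dataclass(frozen=True)
class ViscosityResult:
    eta: float
    stderr: float
    method: str  # green_kubo | mass_scaling | empirical_curve
    cutoff: float | None = None

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


def green_kubo(
    stress,
    dt: float,
    volume: float,
    temperature: float,
    max_lag: int | None = None,
) -> ViscosityResult:
    """Green-Kubo shear viscosity from off-diagonal stress components.

    ``stress`` is (n,) or (n, n_components); components are averaged.  The
    integration cutoff comes from the plateau of the running integral: the
    plateau value is read off as the mean over [t0, 3 t0], where t0 is the
    lag at which the autocorrelation first decays into its noise floor
    (first zero crossing).  stderr is the scatter across components (or
    across time blocks for a single one).
    """
    P = np.atleast_2d(np.asarray(stress, dtype=float))
    if P.shape[0] < P.shape[1]:
        P = P.T
    n, ncomp = P.shape
    if n < 100:
        raise ValueError("stress series too short for a Green-Kubo estimate")
    if max_lag is None:
        max_lag = max(min(int(0.1 * n), n - 2), 10)
    if max_lag > 0.1 * n:
        raise ValueError("cutoff window must be <= 10% of the series duration")

    etas = []
    cutoffs = []
    for c in range(ncomp):
        eta_c, tc = _gk_single(P[:, c], dt, volume, temperature, max_lag)
        etas.append(eta_c)
        cutoffs.append(tc)
    if np.allclose(P, 0.0):
        return ViscosityResult(eta=0.0, stderr=0.0, method="green_kubo", cutoff=0.0)

    if ncomp > 1:
        eta = float(np.mean(etas))
        stderr = float(np.std(etas, ddof=1) / math.sqrt(ncomp))
    else:
        eta = etas[0]
        # block estimate over 5 time slices
        edges = np.linspace(0, n, 6).astype(int)
        vals = []
        for a, b in zip(edges[:-1], edges[1:]):
            try:
                v, _ = _gk_single(
                    P[a:b, 0], dt, volume, temperature,
                    min(max_lag, (b - a) // 3),
                )
                vals.append(v)
            except (NoPlateauError, ValueError):
                continue
        stderr = (
            float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
            if len(vals) >= 3 else 0.0
        )
    return ViscosityResult(
        eta=eta, stderr=stderr, method="green_kubo", cutoff=float(np.mean(cutoffs))
    )


def _gk_single(p, dt, volume, temperature, max_lag):
    p = p - p.mean()
    if np.allclose(p, 0.0):
        return 0.0, 0.0
    from scipy.fft import irfft, next_fast_len, rfft

    n = p.size
    nfft = next_fast_len(n + max_lag + 1)
    fp = rfft(p, nfft)
    acf = irfft(fp * np.conj(fp), nfft)[: max_lag + 1]
    acf /= n - np.arange(max_lag + 1)

    # plateau window: the running integral is flat once the ACF has decayed
    # into its noise floor (first zero crossing at lag t0); averaging over
    # [t0, 3 t0] reads off the plateau without accumulating the random-walk
    # noise of the long-lag correlation estimate
    neg = np.nonzero(acf <= 0.0)[0]
    if neg.size == 0:
        raise NoPlateauError(
            "stress autocorrelation has not decayed within the allowed "
            "window; no running-integral plateau"
        )
    t0 = max(int(neg[0]), 2)
    hi = min(3 * t0, max_lag)
    running = np.concatenate(([0.0], cumulative_trapezoid(acf[: hi + 1], dx=dt)))
    val = float(running[t0 : hi + 1].mean())
    return volume / temperature * val, t0 * dt


def mass_scaled_viscosity(mass_ratio) -> float:
    """Super-heavy-water rule: eta/eta0 = sqrt(m/m0)."""
    mass_ratio = np.asarray(mass_ratio, dtype=float)
    if np.any(mass_ratio <= 0):
        raise ValueError("mass ratio must be > 0")
    out = np.sqrt(mass_ratio)
    return float(out) if out.ndim == 0 else out


def _cheng_coeffs() -> dict:
    with resources.files("glefric.data").joinpath("cheng2008.json").open() as fh:
        return json.load(fh)


def glycerol_empirical_viscosity(
    mass_fraction: float,
    temperature_K: float = 300.0,
) -> ViscosityResult:
    """Cheng empirical viscosity of a water-glycerol mixture, in mPa s.

    eta = eta_w^A * eta_g^(1-A) with a weighting exponent A(Cm, T) and
    Arrhenius-like pure-component branches; valid for 0 <= Cm <= 1 and
    0-100 degC.
    """
    if not (0.0 <= mass_fraction <= 1.0):
        raise ValueError("glycerol mass fraction must be in [0, 1]")
    cfg = _cheng_coeffs()
    T = temperature_K - 273.15
    lo, hi = cfg["validity_celsius"]
    if not (lo <= T <= hi):
        raise ValueError(f"temperature {T:.1f} C outside validity range [{lo}, {hi}] C")

    w = cfg["water_mPas"]
    g = cfg["glycerol_mPas"]
    eta_w = w["prefactor"] * math.exp((w["c1"] - T) * T / (w["c2"] + w["c3"] * T))
    eta_g = g["prefactor"] * math.exp((g["c1"] + T) * T / (g["c2"] + g["c3"] * T))

    cm = mass_fraction
    a = cfg["a"]["a0"] + cfg["a"]["a1"] * T
    b = (cfg["b"]["b0"] + cfg["b"]["b1"] * T) * a ** cfg["b"]["a_power"]
    denom = a * cm + b * (1.0 - cm)
    A = 1.0 - cm + a * b * cm * (1.0 - cm) / denom if denom > 0 else 1.0 - cm
    eta = eta_w**A * eta_g ** (1.0 - A)
    return ViscosityResult(eta=float(eta), stderr=0.0, method="empirical_curve")
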