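"""Model fitting: the parametric kernel model and the viscosity-scaling law.

Two fits are provided.  ``fit_kernel_model`` fits the multi-exponential
(+ one damped-oscillating) kernel model to an extracted running integral
G(t) under the hard constraint that the component amplitudes sum to the
plateau friction gamma.  ``fit_viscosity_scaling`` fits the isomerization
time versus relative solvent viscosity with

    tau(eta) = alpha * (eta/eta0)**beta + epsilon,

whose intercept fraction epsilon/(alpha+epsilon) and exponent beta
diagnose internal-friction-like deviations from Kramers/Stokes-Einstein
scaling (ratio -> 1: dominant offset; beta < 1: sublinear scaling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .extraction import KernelEstimate
from .kernels import MemoryKernel


class FitError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# kernel-model fit


def _log_bin_weights(t: np.ndarray, n_bins: int = 30) -> np.ndarray:
    """Per-point weights making each logarithmic lag bin contribute equally."""
    edges = np.geomspace(t[0], t[-1] * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return 1.0 / np.sqrt(counts[idx])


def fit_kernel_model(
    est: KernelEstimate,
    n_exp: int = 3,
    n_osc: int = 1,
    n_starts: int = 8,
    seed: int = 0,
) -> MemoryKernel:
    """Fit the kernel model to G(t) with amplitudes constrained to gamma.

    The fit runs on G(t) (not on the differentiation-noise-amplified
    Gamma).  Weights are uniform over log-spaced lag bins, additionally
    scaled by the inverse block standard error of G when block estimates
    are available (the correlation-estimate noise grows strongly with lag,
    and ignoring that lets the noisy tail distort the slow time scales).
    Amplitudes are parametrized as gamma * z_i^2 / sum(z^2), which
    enforces nonnegativity and makes the sum equal the plateau friction
    exactly.  Time scales and the oscillation frequency are
    log-parametrized.  The best of ``n_starts`` seeded restarts is
    returned, components sorted by descending time scale.
    """
    if not (0 <= n_exp <= 3) or not (0 <= n_osc <= 1) or n_exp + n_osc == 0:
        raise ValueError("need 0<=n_exp<=3, 0<=n_osc<=1, at least one component")
    if est.gamma is None:
        raise ValueError("estimate has no plateau friction; run plateau_friction first")
    gamma = float(est.gamma)

    t = est.t[1:]
    G = est.G[1:]
    w = _log_bin_weights(t)
    if est.block_G is not None and est.block_G.shape[0] >= 3:
        nb = est.block_G.shape[0]
        se = est.block_G.std(axis=0, ddof=1)[1:] / math.sqrt(nb)
        w = w / (se + 0.002 * abs(gamma))  # floor keeps t->0 weights finite
    n_amp = n_exp + n_osc
    dt = est.dt
    t_max = float(t[-1])

    def unpack(p):
        z = p[:n_amp]
        amps = gamma * z**2 / np.sum(z**2)
        taus = np.exp(p[n_amp : 2 * n_amp])
        omega = np.exp(p[-1]) if n_osc else None
        return amps, taus, omega

    def model(p):
        amps, taus, omega = unpack(p)
        out = np.zeros_like(t)
        for i in range(n_exp):
            out += amps[i] * (1.0 - np.exp(-t / taus[i]))
        if n_osc:
            k = MemoryKernel.from_components(osc=[(amps[-1], taus[-1], omega)])
            out += k.G_of_t(t)
        return out

    def resid(p):
        return w * (model(p) - G)

    rng = np.random.default_rng(seed)
    log_lo, log_hi = math.log(max(dt, 1e-12)), math.log(t_max)
    best = None
    n_params = 2 * n_amp + (1 if n_osc else 0)
    lb = np.full(n_params, -np.inf)
    ub = np.full(n_params, np.inf)
    lb[n_amp : 2 * n_amp] = log_lo - 2.0
    ub[n_amp : 2 * n_amp] = log_hi + 2.0
    if n_osc:
        lb[-1] = math.log(math.pi / t_max)
        ub[-1] = math.log(math.pi / dt)

    for s in range(max(n_starts, 1)):
        z0 = 0.3 + rng.random(n_amp)
        # spread initial time scales over the lag decade range
        logt0 = np.sort(rng.uniform(log_lo + 0.5, log_hi - 0.2, n_amp))[::-1]
        p0 = np.concatenate([z0, logt0])
        if n_osc:
            p0 = np.append(p0, rng.uniform(math.log(2.0 * math.pi / t_max), math.log(1.0 / dt)))
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub), max_nfev=2000)
        except Exception:
            continue
        if sol.cost is not None and np.isfinite(sol.cost):
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitError("kernel-model fit failed to converge from all starts")

    amps, taus, omega = unpack(best.x)
    exp_comps = sorted(
        [(float(amps[i]), float(taus[i])) for i in range(n_exp)],
        key=lambda c: -c[1],
    )
    osc_comps = [(float(amps[-1]), float(taus[-1]), float(omega))] if n_osc else []
    return MemoryKernel.from_components(exp=exp_comps, osc=osc_comps)


def select_n_exp(
    est: KernelEstimate,
    max_exp: int = 3,
    n_osc: int = 0,
    improvement: float = 0.05,
    seed: int = 0,
) -> int:
    """Smallest number of exponentials whose residual improves by less
    than ``improvement`` (relative) when one more is added."""
    costs = {}
    for n in range(1, max_exp + 1):
        k = fit_kernel_model(est, n_exp=n, n_osc=n_osc, seed=seed)
        r = _refit_cost(est, k)
        costs[n] = r
        if n > 1 and (costs[n - 1] - r) < improvement * costs[n - 1]:
            return n - 1
    return max_exp


def _refit_cost(est: KernelEstimate, kernel: MemoryKernel) -> float:
    t = est.t[1:]
    w = _log_bin_weights(t)
    return float(np.sum((w * (kernel.G_of_t(t) - est.G[1:])) ** 2))


# ----------------------------------------------------------------------
# viscosity-scaling fit


@dataclass
class ScalingFit:
    """Parameters of tau(eta) = alpha (eta/eta0)^beta + epsilon."""

    alpha: float
    beta: float
    epsilon: float
    cov: np.ndarray | None = None
    residual_norm: float = np.nan
    n_points: int = 0
    bootstrap: np.ndarray | None = None  # (n_boot, 3) parameter samples

    def __post_init__(self):
        if self.alpha < 0 or self.epsilon < 0:
            raise ValueError("alpha and epsilon must be >= 0")

    @property
    def internal_friction_ratio(self) -> float:
        s = self.alpha + self.epsilon
        if s <= 0:
            raise ValueError("alpha + epsilon must be > 0")
        return self.epsilon / s

    def predict(self, eta_rel):
        eta_rel = np.asarray(eta_rel, dtype=float)
        return self.alpha * eta_rel**self.beta + self.epsilon

    def ratio_ci(self, level: float = 0.90) -> tuple[float, float]:
        if self.bootstrap is None or self.bootstrap.shape[0] < 10:
            raise ValueError("no bootstrap samples available")
        a, b, e = self.bootstrap.T
        with np.errstate(invalid="ignore", divide="ignore"):
            r = e / (a + e)
        r = r[np.isfinite(r)]
        q = (1.0 - level) / 2.0
        return float(np.quantile(r, q)), float(np.quantile(r, 1.0 - q))

    def beta_ci(self, level: float = 0.90) -> tuple[float, float]:
        if self.bootstrap is None or self.bootstrap.shape[0] < 10:
            raise ValueError("no bootstrap samples available")
        b = self.bootstrap[:, 1]
        q = (1.0 - level) / 2.0
        return float(np.quantile(b, q)), float(np.quantile(b, 1.0 - q))


def fit_viscosity_scaling(
    points,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> ScalingFit:
    """Bounded least-squares fit of the viscosity-scaling law.

    ``points`` is an iterable of (eta_rel, tau) or (eta_rel, tau, stderr);
    stderr, when present, enters as inverse-variance weights and drives a
    parametric bootstrap (otherwise the bootstrap resamples points).
    """
    pts = np.atleast_2d(np.asarray(list(points), dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 (eta, tau) points")
    eta = pts[:, 0]
    tau = pts[:, 1]
    err = pts[:, 2] if pts.shape[1] > 2 else None
    if np.any(eta <= 0):
        raise ValueError("eta/eta0 must be > 0")
    if np.allclose(eta, eta[0]):
        raise ValueError("all viscosities identical; scaling not identifiable")

    sol = _fit_scaling_once(eta, tau, err, seed)
    alpha, beta, eps = sol.x

    rng = np.random.default_rng(seed + 1)
    boots = []
    n = eta.size
    for b in range(n_bootstrap):
        if err is not None:
            tau_b = tau + err * rng.standard_normal(n)
            eta_b, err_b = eta, err
        else:
            idx = rng.integers(0, n, n)
            if np.unique(eta[idx]).size < 2:
                continue
            eta_b, tau_b, err_b = eta[idx], tau[idx], None
        try:
            # warm start at the main fit: bootstrap surfaces are small
            # perturbations, so a single seeded restart suffices
            sb = _fit_scaling_once(eta_b, tau_b, err_b, seed + 2 + b,
                                   p0=sol.x, n_extra=1)
            boots.append(sb.x)
        except Exception:
            continue

    jac = sol.jac
    cov = None
    try:
        dof = max(n - 3, 1)
        s2 = 2.0 * sol.cost / dof
        cov = s2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        pass

    return ScalingFit(
        alpha=float(alpha), beta=float(beta), epsilon=float(eps),
        cov=cov, residual_norm=float(np.sqrt(2.0 * sol.cost)),
        n_points=int(n),
        bootstrap=np.asarray(boots) if boots else None,
    )


def _fit_scaling_once(eta, tau, err, seed, p0=None, n_extra=4):
    w = 1.0 / err if err is not None else np.ones_like(tau)

    def resid(p):
        a, b, e = p
        return w * (a * eta**b + e - tau)

    scale = max(float(np.mean(tau)), 1e-12)
    if p0 is not None:
        starts = [tuple(np.maximum(p0, [0.0, -np.inf, 0.0]))]
    else:
        starts = [
            (scale, 1.0, 1e-6),
            (scale / 2.0, 0.5, scale / 2.0),
            (1e-6 * scale, 1.0, scale),
            (scale, 0.2, 1e-6),
        ]
    rng = np.random.default_rng(seed)
    for _ in range(n_extra):
        starts.append(
            (scale * rng.random(), rng.uniform(-0.5, 2.0), scale * rng.random())
        )
    best = None
    for p0 in starts:
        try:
            sol = least_squares(
                resid, p0, bounds=([0.0, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("viscosity-scaling fit failed")
    return best


def internal_friction_ratio(fit: ScalingFit, level: float = 0.90):
    """epsilon / (alpha + epsilon) with a bootstrap confidence interval."""
    r = fit.internal_friction_ratio
    try:
        ci = fit.ratio_ci(level)
    except ValueError:
        ci = None
    return r, ci
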