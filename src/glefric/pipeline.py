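"""End-to-end analysis pipeline.

Chains the stages profile -> mass -> kernel extraction -> kernel-model fit
-> first-passage times -> rate-theory predictions over a single
trajectory (read from disk or simulated from the config), writing every
artifact with a provenance sidecar (config hash, seed, package version).
Re-running with an unchanged config reproduces the outputs exactly.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .extraction import extract_kernel
from .io import (
    read_profile,
    read_timeseries,
    write_json,
    write_kernel_estimate,
    write_profile,
    write_trajectory,
)
from .kinetics import first_passage_times
from .models import fit_kernel_model
from .potentials import make_potential
from .profiles import barrier_descriptor, estimate_free_energy, estimate_mass
from .rate_theory import (
    diffusion_time,
    grote_hynes,
    kramers_overdamped,
    memory_regime,
)
from .simulate import simulate_gle

log = logging.getLogger("glefric")


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {exc}")


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                log.info("stage %s", name)
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def pipeline_run(config: RunConfig) -> dict:
    """Execute the full workflow described by ``config``.

    Returns a result bundle (dict of stage outputs); all artifacts are
    written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = config.to_text()
    provenance = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "config.txt").write_text(cfg_text)
    bundle: dict = {"provenance": provenance}

    traj = _load_or_simulate(config)
    bundle["trajectory"] = traj
    write_trajectory(traj, out / "trajectory.dat")

    profile = _profile_stage(config, traj)
    bundle["profile"] = profile
    write_profile(profile, out / "profile.dat")

    mass = _mass_stage(config, traj)
    bundle["mass"] = mass
    log.info("effective mass m=%.6g", mass)

    est = _extract_stage(config, traj, profile, mass)
    bundle["kernel_estimate"] = est
    write_kernel_estimate(est, out / "kernel.dat")
    log.info("plateau friction gamma=%.6g +- %.2g", est.gamma, est.gamma_stderr)

    kernel = _fit_stage(config, est)
    bundle["kernel_model"] = kernel
    write_json(kernel.describe(), out / "kernel_fit.json")

    rates = _rates_stage(config, profile, est, kernel, mass, traj)
    bundle["rates"] = rates
    write_json(rates, out / "rates.json")

    write_json(provenance, out / "provenance.json")
    return bundle


@_stage("input")
def _load_or_simulate(config: RunConfig):
    if config.trajectory:
        return read_timeseries(config.trajectory, kind=config.coordinate_kind)
    if not config.potential:
        raise ValueError("config needs either a trajectory path or a potential")
    kernel = config.parsed_kernel()
    if kernel is None:
        raise ValueError("synthetic run needs kernel components")
    prof = _make_cfg_potential(config)
    mass = config.mass if config.mass else 1.0
    log.info(
        "simulating %d steps, dt=%g, potential=%s, gamma=%g",
        config.n_steps, config.dt, config.potential, kernel.total_friction,
    )
    return simulate_gle(
        prof, kernel, mass=mass, temperature=config.temperature,
        dt=config.dt, n_steps=config.n_steps, seed=config.seed,
    )


def _make_cfg_potential(config: RunConfig):
    kw = {}
    if config.potential in ("cosine_dihedral", "double_well_quartic"):
        kw["barrier"] = config.barrier
    if config.potential == "cosine_dihedral" and config.gauche_offset:
        kw["gauche_offset"] = config.gauche_offset
    if config.potential == "harmonic":
        kw["k"] = config.barrier or 1.0
    return make_potential(config.potential, **kw)


@_stage("profile")
def _profile_stage(config: RunConfig, traj):
    if config.profile and config.profile != "auto":
        return read_profile(config.profile)
    log.info("estimating free energy: %d bins", config.bins)
    return estimate_free_energy(traj, n_bins=config.bins)


@_stage("mass")
def _mass_stage(config: RunConfig, traj):
    if config.mass:
        return float(config.mass)
    return estimate_mass(traj).m


@_stage("extract")
def _extract_stage(config: RunConfig, traj, profile, mass):
    log.info("extraction: max_lag=%s plateau_tol=%g", config.max_lag, config.plateau_tol)
    return extract_kernel(
        traj, profile, mass=mass, max_lag=config.max_lag, tol=config.plateau_tol
    )


@_stage("fit-kernel")
def _fit_stage(config: RunConfig, est):
    return fit_kernel_model(
        est, n_exp=config.n_exp_fit, n_osc=config.n_osc_fit, seed=config.seed
    )


@_stage("rates")
def _rates_stage(config: RunConfig, profile, est, kernel, mass, traj):
    mins = profile.minima
    if len(mins) < 2 or not profile.maxima:
        return {"note": "no barrier in profile; rate predictions skipped"}
    src = config.mfpt_source
    tgt = config.mfpt_target
    if src is None or tgt is None:
        by_depth = sorted(mins, key=lambda s: float(profile.energy(s.position)))
        tgt = by_depth[0].position
        src = by_depth[1].position
    u0, c_min, c_max, L = barrier_descriptor(profile, src, tgt)
    gamma = est.gamma
    kr = kramers_overdamped(gamma, u0, c_min, c_max, temperature=traj.temperature)
    gh = grote_hynes(kernel, mass, c_min, c_max, u0, temperature=traj.temperature)
    out = {
        "barrier": {"U0": u0, "curv_min": c_min, "curv_max": c_max, "L": L},
        "gamma": gamma,
        "kramers_overdamped": kr.time,
        "grote_hynes": gh.time,
        "reactive_frequency": gh.reactive_frequency,
        "tau_D": diffusion_time(gamma, L, traj.temperature),
        "memory_regime": memory_regime(kernel, gamma, L, traj.temperature),
    }
    try:
        fpt = first_passage_times(
            traj, src, tgt, pool_symmetric=config.pool_symmetric, seed=config.seed
        )
        out["tau_mfp"] = fpt.mean
        out["tau_mfp_stderr"] = fpt.stderr
        out["n_events"] = fpt.n_events
    except Exception as exc:  # too few events is a legitimate outcome
        out["tau_mfp_error"] = str(exc)
    return out
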