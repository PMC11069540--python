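"""Readers and writers for scalar time-series and analysis artifacts.

Trajectories travel as plain two-column ASCII "time value" files with a
header line

    # dt=<ps> temperature=<kBT> periodic=<0|1> period=<...> kind=<angle|distance>

written at 17 significant digits so that a write -> read round trip is
bit-exact.  The reader also accepts the GROMACS xvg dialect (lines
starting with '#' or '@' are comments) and NumPy .npy/.npz containers.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .trajectory import Trajectory

_FMT = "%.17g"


def write_trajectory(traj: Trajectory, path) -> Path:
    path = Path(path)
    header = (
        f"dt={traj.dt!r} temperature={traj.temperature!r} "
        f"periodic={1 if traj.periodic else 0} "
        f"period={traj.period if traj.period is not None else 'none'} "
        f"kind={traj.kind}"
    )
    data = np.column_stack([traj.times, traj.values])
    np.savetxt(path, data, fmt=_FMT, header=header, comments="# ")
    return path


def _parse_header(lines) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#@ \t").strip()
        for tok in body.split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    return meta


def read_timeseries(
    path,
    dialect: str = "auto",
    dt: float | None = None,
    kind: str | None = None,
    periodic: bool | None = None,
    period: float | None = None,
    temperature: float = 1.0,
) -> Trajectory:
    """Read a scalar time series as a :class:`Trajectory`.

    ``dialect`` is one of "plain2col", "xvg", "npy", or "auto" (sniffed
    from the suffix/content).  The timestep is inferred from the time
    column (uniformity enforced to 1e-6 relative) unless declared in the
    header or overridden.  Angles are wrapped into the principal interval.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time series not found: {path}")

    if dialect == "auto":
        if path.suffix in (".npy", ".npz"):
            dialect = "npy"
        elif path.suffix == ".xvg":
            dialect = "xvg"
        else:
            dialect = "plain2col"

    if dialect == "npy":
        obj = np.load(path)
        if isinstance(obj, np.lib.npyio.NpzFile):
            values = np.asarray(obj["values"], dtype=float)
            file_dt = float(obj["dt"]) if "dt" in obj else None
            meta = {k: obj[k] for k in obj.files if k not in ("values",)}
        else:
            arr = np.atleast_2d(np.asarray(obj, dtype=float))
            if arr.shape[0] == 2 and arr.shape[1] != 2:
                arr = arr.T
            if arr.shape[1] == 2:
                return _from_columns(arr[:, 0], arr[:, 1], {}, dt, kind, periodic, period, temperature)
            values = arr.ravel()
            file_dt, meta = None, {}
        use_dt = dt or file_dt
        if use_dt is None:
            raise ValueError(f"{path}: no timestep in container and no dt override")
        return _build(values, use_dt, {}, kind, periodic, period, temperature)

    comment_lines = []
    rows = []
    with open(path) as fh:
        for ln in fh:
            s = ln.strip()
            if not s:
                continue
            if s.startswith("#") or (dialect == "xvg" and s.startswith("@")):
                comment_lines.append(s)
                continue
            if s.startswith("@"):
                raise ValueError(
                    f"{path}: '@' directive found; use dialect='xvg' for GROMACS files"
                )
            rows.append(s.split())
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    meta = _parse_header(comment_lines)
    if data.shape[1] == 1:
        use_dt = dt or (float(meta["dt"]) if "dt" in meta else None)
        if use_dt is None:
            raise ValueError(f"{path}: single-column file needs dt in header or override")
        return _build(data[:, 0], use_dt, meta, kind, periodic, period, temperature)
    return _from_columns(data[:, 0], data[:, 1], meta, dt, kind, periodic, period, temperature)


def _from_columns(t, values, meta, dt, kind, periodic, period, temperature):
    steps = np.diff(t)
    if steps.size == 0:
        raise ValueError("need at least 2 samples")
    dt_est = float(np.mean(steps))
    if dt_est <= 0 or np.max(np.abs(steps - dt_est)) > 1e-6 * abs(dt_est):
        raise ValueError(
            f"non-uniform sampling: time steps vary by more than 1e-6 "
            f"relative (mean {dt_est:g})"
        )
    use_dt = dt if dt is not None else (float(meta["dt"]) if "dt" in meta else dt_est)
    return _build(values, use_dt, meta, kind, periodic, period, temperature)


def _build(values, dt, meta, kind, periodic, period, temperature):
    m_kind = meta.get("kind")
    m_periodic = meta.get("periodic")
    m_period = meta.get("period")
    m_temp = meta.get("temperature")
    kind = kind or m_kind
    if kind is None:
        raise ValueError(
            "coordinate kind is ambiguous: no 'kind=' header and no override "
            "(pass kind='angle' or kind='distance')"
        )
    if periodic is None:
        periodic = bool(int(m_periodic)) if m_periodic is not None else (kind == "angle")
    if period is None and m_period not in (None, "none"):
        period = float(m_period)
    if period is None and periodic:
        period = 2.0 * math.pi
    temp = float(m_temp) if m_temp is not None else temperature
    return Trajectory(
        values=np.asarray(values, dtype=float),
        dt=float(dt),
        temperature=temp,
        periodic=periodic,
        period=period,
        kind=kind,
    )


# ----------------------------------------------------------------------


def write_profile(profile, path) -> Path:
    """Two-column (q, U) ASCII with units/periodicity header."""
    path = Path(path)
    header = (
        f"units=kBT periodic={1 if profile.periodic else 0} "
        f"period={profile.period if profile.period is not None else 'none'} "
        f"provenance={profile.provenance}"
    )
    np.savetxt(path, np.column_stack([profile.q, profile.u]), fmt=_FMT,
               header=header, comments="# ")
    return path


def read_profile(path):
    from .potentials import make_potential

    path = Path(path)
    comment_lines = []
    rows = []
    with open(path) as fh:
        for ln in fh:
            s = ln.strip()
            if not s:
                continue
            if s.startswith("#"):
                comment_lines.append(s)
            else:
                rows.append(s.split())
    data = np.asarray(rows, dtype=float)
    meta = _parse_header(comment_lines)
    periodic = bool(int(meta.get("periodic", 0)))
    period = None
    if meta.get("period") not in (None, "none"):
        period = float(meta["period"])
    return make_potential(
        "tabulated", q=data[:, 0], u=data[:, 1], periodic=periodic, period=period
    )


def write_kernel_estimate(est, path) -> Path:
    """Three-column (t, G, Gamma) ASCII plus a JSON sidecar with the
    plateau friction, stderr, window and settings."""
    path = Path(path)
    np.savetxt(path, np.column_stack([est.t, est.G, est.Gamma]), fmt=_FMT,
               header="t G Gamma", comments="# ")
    sidecar = {
        "gamma": est.gamma,
        "gamma_stderr": est.gamma_stderr,
        "window": list(est.window) if est.window else None,
        "mass": est.mass,
        "diagnostics": {k: _jsonable(v) for k, v in est.diagnostics.items()},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
    return path


def _jsonable(v):
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v
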