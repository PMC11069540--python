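"""Mean first-passage times and translational diffusion.

First-passage events are counted with a renewal (alternating) construction
that eliminates state-recrossing effects: an event begins at the first
crossing of the source position after the previous arrival at the target
(the very first event begins at the first source crossing), and ends at
the first subsequent crossing of the target.  Rapid recrossings of the
source inside an open event do not spawn new events.  Crossing times are
interpolated linearly between the bracketing samples, and angle
coordinates use minimum-image arithmetic throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory
from .units import minimum_image


class NoEventsError(RuntimeError):
    pass


@dataclass
class FPTResult:
    """First-passage events between a source and a target position."""

    times: np.ndarray           # event durations, ps
    source: float
    target: float
    direction: str = ""
    stderr: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size == 0:
            raise NoEventsError("no completed first-passage events")

    @property
    def mean(self) -> float:
        return float(self.times.mean())

    @property
    def n_events(self) -> int:
        return int(self.times.size)


def _crossing_times(q, dt, position, periodic, period, halfwidth=0.0):
    """Times at which the series reaches ``position`` (or enters the core
    region of half-width ``halfwidth`` around it), linearly interpolated."""
    if periodic:
        d = minimum_image(q - position, period)
    else:
        d = q - position
    if halfwidth > 0.0:
        d = np.abs(d) - halfwidth  # entering the core = downward crossing of 0
    s = np.signbit(d)
    flips = np.nonzero(s[1:] != s[:-1])[0]
    if periodic:
        # a sign flip with a jump larger than half the distance range is the
        # antipode wrapping, not a crossing of `position`
        jump = np.abs(d[flips + 1] - d[flips])
        flips = flips[jump < period / 2.0]
    d0 = d[flips]
    d1 = d[flips + 1]
    frac = d0 / (d0 - d1)
    return (flips + frac) * dt


def first_passage_times(
    traj: Trajectory,
    q_source: float,
    q_target: float,
    pool_symmetric: bool = False,
    core_halfwidth: float = 0.0,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> FPTResult:
    """First-passage times from ``q_source`` to ``q_target``.

    ``pool_symmetric`` additionally counts crossings of ``-q_source``
    (the mirrored gauche state of a symmetric dihedral) as source
    crossings.  ``core_halfwidth`` switches from point targets to core
    regions of the given half-width (sensitivity variant).  The standard
    error of the mean is a seeded moving-block bootstrap over events.
    """
    q = traj.values
    lo, hi = q.min(), q.max()

    def _check_support(x):
        if traj.periodic:
            return  # any angle is inside the periodic support
        if not (lo <= x <= hi):
            raise ValueError(f"position {x:g} outside sampled range [{lo:g}, {hi:g}]")

    _check_support(q_source)
    _check_support(q_target)

    src_times = _crossing_times(q, traj.dt, q_source, traj.periodic, traj.period, core_halfwidth)
    if pool_symmetric:
        mirrored = _crossing_times(q, traj.dt, -q_source, traj.periodic, traj.period, core_halfwidth)
        src_times = np.sort(np.concatenate([src_times, mirrored]))
    tgt_times = _crossing_times(q, traj.dt, q_target, traj.periodic, traj.period, core_halfwidth)

    events = _alternate(src_times, tgt_times)
    if events.size == 0:
        occupancy = {
            "n_source_crossings": int(src_times.size),
            "n_target_crossings": int(tgt_times.size),
            "range": (float(lo), float(hi)),
        }
        raise NoEventsError(f"zero completed events; diagnostics: {occupancy}")

    res = FPTResult(
        times=events,
        source=q_source,
        target=q_target,
        direction=f"{q_source:g}->{q_target:g}",
    )
    res.stderr = _block_bootstrap_stderr(events, n_bootstrap, seed)
    return res


def _alternate(src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """Renewal alternation: next source crossing after last target arrival."""
    events = []
    t_ready = -np.inf  # arrival time after which the next event may start
    i = j = 0
    ns, nt = src.size, tgt.size
    while True:
        i = np.searchsorted(src, t_ready, side="right")
        if i >= ns:
            break
        t_start = src[i]
        j = np.searchsorted(tgt, t_start, side="right")
        if j >= nt:
            break
        t_end = tgt[j]
        events.append(t_end - t_start)
        t_ready = t_end
    return np.asarray(events)


def _block_bootstrap_stderr(x: np.ndarray, n_boot: int, seed: int, block: int | None = None) -> float:
    n = x.size
    if n < 2:
        return float("nan")
    if block is None:
        block = max(1, int(round(n ** (1.0 / 3.0))))
    rng = np.random.default_rng(seed)
    n_blocks = max(1, int(math.ceil(n / block)))
    means = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, n - block + 1, size=n_blocks) if n > block else np.zeros(n_blocks, dtype=int)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
        means[b] = x[idx].mean()
    return float(means.std(ddof=1))


# ----------------------------------------------------------------------


def translational_diffusion(
    data,
    dt: float | None = None,
    dimensionality: int | None = None,
    fit_window: tuple | None = None,
    n_lags: int = 60,
):
    """Translational diffusion coefficient from an MSD slope.

    Parameters
    ----------
    data :
        Either an (n, d) array of positions (requires ``dt``) or a tuple
        ``(t, msd)`` of a precomputed mean-squared displacement.
    fit_window : (t_lo, t_hi), optional
        Lag-time window for the linear fit; defaults to the upper half of
        the computed lags.

    Returns
    -------
    D : float
        slope / (2 * dimensionality).
    """
    if isinstance(data, tuple):
        t, msd = (np.asarray(a, dtype=float) for a in data)
        if dimensionality is None:
            raise ValueError("dimensionality required for a precomputed MSD")
        drops = np.diff(msd) < -1e-9 * max(msd.max(), 1e-300)
        if drops.any():
            raise ValueError("MSD is not monotonically increasing: not an MSD")
    else:
        pos = np.atleast_2d(np.asarray(data, dtype=float))
        if pos.shape[0] < pos.shape[1]:
            pos = pos.T
        if dt is None:
            raise ValueError("dt required for a position series")
        if dimensionality is None:
            dimensionality = pos.shape[1]
        n = pos.shape[0]
        # cap lags at 1% of the series: longer lags have few independent
        # segments and their noise would dominate the slope fit
        lags = np.unique(np.geomspace(1, max(n // 100, 10), n_lags).astype(int))
        msd = np.array(
            [np.mean(np.sum((pos[k:] - pos[:-k]) ** 2, axis=1)) for k in lags]
        )
        t = lags * dt

    if fit_window is None:
        fit_window = (t[max(1, t.size // 2)], t[-1])
    sel = (t >= fit_window[0]) & (t <= fit_window[1])
    if sel.sum() < 2:
        raise ValueError("fit window selects fewer than 2 MSD points")
    slope = np.polyfit(t[sel], msd[sel], 1)[0]
    return slope / (2.0 * dimensionality)


# ----------------------------------------------------------------------


def mfpt_vs_condition(entries, reference: str) -> pd.DataFrame:
    """Tidy table of first-passage times across solvent conditions.

    Parameters
    ----------
    entries :
        Iterable of (label, eta_rel, result) where ``result`` is either an
        :class:`FPTResult` or a (tau, stderr) pair.
    reference : str
        Label of the reference condition (e.g. neat water); ratios
        tau / tau_ref are added with relative errors combined in
        quadrature.
    """
    rows = []
    for label, eta, res in entries:
        if isinstance(res, FPTResult):
            tau, err, n_ev = res.mean, res.stderr, res.n_events
        else:
            tau, err = res
            n_ev = None
        rows.append(
            {"condition": label, "eta_rel": float(eta), "tau_mfp": float(tau),
             "tau_stderr": float(err) if err is not None else np.nan,
             "n_events": n_ev}
        )
    df = pd.DataFrame(rows)
    ref = df[df["condition"] == reference]
    if ref.empty:
        raise ValueError(f"reference condition {reference!r} not present")
    tau0 = float(ref["tau_mfp"].iloc[0])
    err0 = float(ref["tau_stderr"].iloc[0])
    df["tau_ratio"] = df["tau_mfp"] / tau0
    rel = np.sqrt(
        (df["tau_stderr"] / df["tau_mfp"]) ** 2 + (err0 / tau0) ** 2
    )
    df["tau_ratio_stderr"] = df["tau_ratio"] * rel
    df.loc[df["condition"] == reference, "tau_ratio"] = 1.0
    return df
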