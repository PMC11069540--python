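"""Scalar reaction-coordinate trajectory container."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import wrap_angle

TWO_PI = 2.0 * math.pi


@dataclass
class Trajectory:
    """Uniformly sampled scalar time series q(t).

    Attributes
    ----------
    values : ndarray
        Samples q_k; sample k is at time k * dt.  Periodic coordinates are
        stored wrapped into the principal interval [-period/2, period/2).
    dt : float
        Timestep in ps.
    temperature : float
        Thermal energy in k_BT units (1.0 for reduced-unit data).
    periodic : bool
    period : float or None
    kind : {"angle", "distance"}
    mass : float or None
        Known effective mass (fixtures), k_BT ps^2 / unit^2.
    kernel : MemoryKernel or None
        Known memory kernel (fixtures).
    seed : int or None
        Seed used to generate the trajectory, when simulated.
    """

    values: np.ndarray
    dt: float
    temperature: float = 1.0
    periodic: bool = False
    period: float | None = None
    kind: str = "distance"
    mass: float | None = None
    kernel: object | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trajectory needs a 1D series of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory contains non-finite values")
        if self.dt <= 0:
            raise ValueError("timestep must be > 0")
        if self.kind not in ("angle", "distance"):
            raise ValueError("coordinate kind must be 'angle' or 'distance'")
        if self.periodic:
            if not self.period:
                self.period = TWO_PI
            self.values = wrap_angle(self.values, self.period)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return (self.values.size - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    def decimate(self, factor: int) -> "Trajectory":
        """Keep every ``factor``-th sample (timestep grows accordingly)."""
        if factor < 1:
            raise ValueError("decimation factor must be >= 1")
        return Trajectory(
            values=self.values[::factor].copy(),
            dt=self.dt * factor,
            temperature=self.temperature,
            periodic=self.periodic,
            period=self.period,
            kind=self.kind,
            mass=self.mass,
            kernel=self.kernel,
            seed=self.seed,
            meta=dict(self.meta),
        )
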