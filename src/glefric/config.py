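"""Flat key-value run configuration.

The config file format is deliberately minimal: one ``key = value`` pair
per line, '#' comments, no nesting.  Unknown keys are rejected with an
error that lists them, and a config round-trips losslessly through
serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class RunConfig:
    # inputs
    trajectory: str | None = None
    profile: str | None = None          # path, or "auto" to estimate
    coordinate_kind: str = "angle"
    # synthetic input (used when no trajectory path is given)
    potential: str | None = None        # e.g. "cosine_dihedral"
    barrier: float | None = None
    gauche_offset: float = 0.0
    kernel_exp: str = ""                # "gamma:tau,gamma:tau,..."
    kernel_osc: str = ""                # "gamma:tau:omega"
    mass: float | None = None           # None -> estimate from data
    dt: float = 0.001
    n_steps: int = 1_000_000
    temperature: float = 1.0
    # analysis parameters
    bins: int = 360
    max_lag: int | None = None
    plateau_tol: float = 0.01
    n_exp_fit: int = 3
    n_osc_fit: int = 1
    mfpt_source: float | None = None
    mfpt_target: float | None = None
    pool_symmetric: bool = False
    # bookkeeping
    seed: int = 0
    out_dir: str = "glefric_out"
    log_level: str = "INFO"

    _BOOLS = ("pool_symmetric",)

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            if f.name.startswith("_"):
                continue
            v = getattr(self, f.name)
            if v is None:
                v = "none"
            elif isinstance(v, bool):
                v = int(v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_text())
        return path

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        known = {f.name: f for f in fields(cls) if not f.name.startswith("_")}
        values = {}
        unknown = []
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                unknown.append(key)
                continue
            values[key] = _coerce(cls, key, val)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(set(unknown))}")
        return cls(**values)

    def parsed_kernel(self):
        from .kernels import MemoryKernel

        exp = []
        for tok in filter(None, (s.strip() for s in self.kernel_exp.split(","))):
            g, t = (float(x) for x in tok.split(":"))
            exp.append((g, t))
        osc = []
        for tok in filter(None, (s.strip() for s in self.kernel_osc.split(","))):
            g, t, w = (float(x) for x in tok.split(":"))
            osc.append((g, t, w))
        if not exp and not osc:
            return None
        return MemoryKernel.from_components(exp=exp, osc=osc)


def _coerce(cls, key: str, val: str):
    if val.lower() == "none":
        return None
    if val == "":
        return ""
    if key in RunConfig._BOOLS:
        return val.lower() in ("1", "true", "yes")
    proto = cls.__dataclass_fields__[key].default
    ann = cls.__dataclass_fields__[key].type
    if "int" in str(ann) and "float" not in str(ann):
        try:
            return int(val)
        except ValueError:
            pass
    if "float" in str(ann):
        try:
            return float(val)
        except ValueError:
            pass
    if isinstance(proto, bool):
        return val.lower() in ("1", "true", "yes")
    if isinstance(proto, int) and not isinstance(proto, bool):
        return int(val)
    if isinstance(proto, float):
        return float(val)
    return val
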