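"""Flat key=value configuration for pipeline runs.

The config format is intentionally minimal: one ``key = value`` pair per
line, ``#`` comments, keys named exactly after the dataclass fields of the
program / circuit / switch / toxin parameter types.  A toxin key switches
the run into consortium mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

from .circuit import CircuitParams
from .programs import InputProgram
from .simulate import ToxinParams
from .switch import SwitchParams

__all__ = ["ConfigError", "PipelineConfig", "parse_flat_config"]


class ConfigError(ValueError):
    pass


def _coerce(raw: str):
    raw = raw.strip()
    low = raw.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        pass
    return raw.strip("\"'")


def parse_flat_config(path) -> dict:
    out: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            out[key.strip()] = _coerce(val)
    return out


_PROGRAM_KEYS = {f.name for f in fields(InputProgram)}
_CIRCUIT_KEYS = {f.name for f in fields(CircuitParams)}
_SWITCH_KEYS = {f.name for f in fields(SwitchParams)}
_TOXIN_KEYS = {f.name for f in fields(ToxinParams)}
_RUN_KEYS = {
    "seed", "n_communities", "outdir", "min_prominence", "nups", "ndowns",
    "cycle_coverage", "traces_path", "consortium",
}


@dataclass
class PipelineConfig:
    """Fully resolved configuration of one pipeline run."""

    program: InputProgram
    circuit: CircuitParams = field(default_factory=CircuitParams)
    switch: SwitchParams = field(default_factory=SwitchParams)
    toxin: Optional[ToxinParams] = None
    n_communities: int = 46
    seed: Optional[int] = None
    outdir: Optional[str] = None
    traces_path: Optional[str] = None
    min_prominence: float = 0.1
    nups: int = 6
    ndowns: int = 6
    cycle_coverage: float = 0.9

    def __post_init__(self) -> None:
        if self.traces_path is None and self.seed is None:
            raise ConfigError("a seed is mandatory for any stochastic run")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - _PROGRAM_KEYS - _CIRCUIT_KEYS - _SWITCH_KEYS - _TOXIN_KEYS - _RUN_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        prog_kwargs = {k: d.pop(k) for k in list(d) if k in _PROGRAM_KEYS}
        circ_kwargs = {k: d.pop(k) for k in list(d) if k in _CIRCUIT_KEYS}
        sw_kwargs = {k: d.pop(k) for k in list(d) if k in _SWITCH_KEYS}
        tox_kwargs = {k: d.pop(k) for k in list(d) if k in _TOXIN_KEYS}
        consortium = bool(d.pop("consortium", False)) or bool(tox_kwargs)
        required = {"period_h", "pulse_width_h", "amplitude_SA", "amplitude_IAA"}
        missing = required - set(prog_kwargs)
        if missing and "traces_path" not in d:
            raise ConfigError(f"missing program key(s): {', '.join(sorted(missing))}")
        program = InputProgram(**prog_kwargs)
        return cls(
            program=program,
            circuit=CircuitParams(**circ_kwargs),
            switch=SwitchParams(**sw_kwargs),
            toxin=ToxinParams(**tox_kwargs) if consortium else None,
            **d,
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_dict(parse_flat_config(path))

    def to_dict(self) -> dict:
        from dataclasses import asdict

        out = {
            "program": self.program.to_dict(),
            "circuit": asdict(self.circuit),
            "switch": asdict(self.switch),
            "toxin": asdict(self.toxin) if self.toxin is not None else None,
            "n_communities": self.n_communities,
            "seed": self.seed,
            "traces_path": self.traces_path,
            "min_prominence": self.min_prominence,
            "nups": self.nups,
            "ndowns": self.ndowns,
            "cycle_coverage": self.cycle_coverage,
        }
        return out
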