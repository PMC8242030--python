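"""Chemical input programs: rectangular SA/IAA rhythms delivered to the chip.

An :class:`InputProgram` describes the periodic chemical environment used in
the microfluidics experiments: auxin (IAA) pulses of ``pulse_width_h`` hours
at the start of every ``period_h``-hour cycle, with salicylic acid (SA)
either antiphase (ON exactly when IAA is OFF, the dual-receptor clock) or
in phase with IAA (used with one amplitude set to zero for single-receptor
pulse-response experiments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["InputProgram", "ProgramError", "make_input_program", "sample_program"]


class ProgramError(ValueError):
    """Invalid chemical-program specification."""


def _commensurate(total_min: float, dt_min: float) -> bool:
    n = total_min / dt_min
    return abs(n - round(n)) < 1e-9


@dataclass(frozen=True)
class InputProgram:
    """A rectangular SA/IAA rhythm.

    Parameters
    ----------
    period_h : float
        Cycle length in hours.
    pulse_width_h : float
        ON duration of the IAA pulse per cycle, hours.
    amplitude_SA, amplitude_IAA : float
        Pulse amplitudes in micromolar.
    antiphase : bool
        If True, SA is ON exactly when IAA is OFF; otherwise SA shares the
        IAA window.
    duration_h : float
        Total record length, hours.
    dt_min : float
        Sampling step in minutes (imaging cadence).
    """

    period_h: float
    pulse_width_h: float
    amplitude_SA: float
    amplitude_IAA: float
    antiphase: bool = True
    duration_h: float = 72.0
    dt_min: float = 10.0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ProgramError(f"period_h must be positive, got {self.period_h}")
        if not (0 < self.pulse_width_h <= self.period_h):
            raise ProgramError(
                f"pulse_width_h must satisfy 0 < width <= period, got "
                f"{self.pulse_width_h} with period {self.period_h}"
            )
        if self.duration_h < self.period_h:
            raise ProgramError("duration_h must cover at least one period")
        if self.dt_min <= 0:
            raise ProgramError(f"dt_min must be positive, got {self.dt_min}")
        if self.amplitude_SA < 0 or self.amplitude_IAA < 0:
            raise ProgramError("amplitudes must be non-negative")
        if not _commensurate(60.0 * self.period_h, self.dt_min):
            raise ProgramError(
                f"dt_min={self.dt_min} does not divide the period "
                f"({self.period_h} h); refusing to round silently"
            )
        if not _commensurate(60.0 * self.duration_h, self.dt_min):
            raise ProgramError(
                f"dt_min={self.dt_min} does not divide duration_h={self.duration_h}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(60.0 * self.duration_h / self.dt_min))

    @property
    def n_cycles(self) -> int:
        """Number of complete cycles contained in the record."""
        return int(np.floor(self.duration_h / self.period_h + 1e-9))

    def time_min(self, dt_min: float | None = None) -> np.ndarray:
        dt = self.dt_min if dt_min is None else dt_min
        n = int(round(60.0 * self.duration_h / dt))
        return np.arange(n) * dt

    def to_dict(self) -> dict:
        return {
            "period_h": self.period_h,
            "pulse_width_h": self.pulse_width_h,
            "amplitude_SA": self.amplitude_SA,
            "amplitude_IAA": self.amplitude_IAA,
            "antiphase": self.antiphase,
            "duration_h": self.duration_h,
            "dt_min": self.dt_min,
        }


def sample_program(
    program: InputProgram, dt_min: float | None = None
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the rectangular waveforms on a uniform grid.

    Returns ``(time_min, c_SA, c_IAA)``; the grid covers ``[0, duration)``
    so a 4-h record at 10-min steps has 24 samples.  IAA is ON on
    ``[k*T, k*T + pulse_width)``; concentrations are exactly 0 or the stated
    amplitude.
    """
    dt = program.dt_min if dt_min is None else dt_min
    if dt <= 0:
        raise ProgramError("sampling step must be positive")
    if not _commensurate(60.0 * program.period_h, dt):
        raise ProgramError(f"step {dt} min is not commensurate with the period")
    t = program.time_min(dt)
    phase = np.mod(t, 60.0 * program.period_h)
    # half-open windows: a sample exactly at the pulse edge belongs to OFF
    iaa_on = phase < 60.0 * program.pulse_width_h - 1e-9
    sa_on = ~iaa_on if program.antiphase else iaa_on
    c_iaa = np.where(iaa_on, program.amplitude_IAA, 0.0)
    c_sa = np.where(sa_on, program.amplitude_SA, 0.0)
    return t, c_sa, c_iaa


def make_input_program(
    period_h: float,
    pulse_width_h: float,
    amplitude_SA: float,
    amplitude_IAA: float,
    antiphase: bool = True,
    duration_h: float = 72.0,
    dt_min: float = 10.0,
) -> Tuple[InputProgram, np.ndarray, np.ndarray, np.ndarray]:
    """Build a program and return it with its sampled waveforms.

    Returns ``(program, time_min, c_SA, c_IAA)``.
    """
    program = InputProgram(
        period_h=period_h,
        pulse_width_h=pulse_width_h,
        amplitude_SA=amplitude_SA,
        amplitude_IAA=amplitude_IAA,
        antiphase=antiphase,
        duration_h=duration_h,
        dt_min=dt_min,
    )
    t, c_sa, c_iaa = sample_program(program)
    return program, t, c_sa, c_iaa
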