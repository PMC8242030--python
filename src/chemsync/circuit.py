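"""Receptor circuit parameters and the chemical-to-drive mapping.

The dual-receptor circuit senses IAA through an activating module and SA
through a repressing one.  We collapse both into a single effective drive

    u_raw(t) = Hill_IAA(c_IAA) - Hill_SA(c_SA)  in [-1, 1],

low-pass filtered with a first-order sensing relaxation (time constant
``tau_u_h``), which is the minimal description consistent with the rapid
activation and hour-scale decay of the reporter bursts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CircuitParams", "CircuitError", "chemical_to_drive"]


class CircuitError(ValueError):
    """Invalid circuit parameters or concentrations."""


@dataclass(frozen=True)
class CircuitParams:
    """Phenomenological parameters of the sensing/reporter circuit.

    EC50 defaults are the fitted receptor midpoints (0.13 uM for the IAA
    module, 407.3 uM for the SA module).  ``alpha`` is the maximal dEGFP
    production rate (a.u./h); ``basal_frac`` the leaky fraction of it;
    ``reporter_halflife_h`` the destabilized-GFP protein half-life;
    ``growth_dilution_h`` the dilution rate from exponential growth (1/h);
    ``extrinsic_cv`` the community-to-community lognormal CV applied to the
    expression amplitudes (``alpha``, ``mcherry_level``); ``measurement_cv``
    the multiplicative measurement noise on the constitutive mCherry
    channel.  ``feedback_mode`` selects open loop (OL), negative (NFL) or
    positive (PFL) phenomenological production-rate feedback with gain
    ``feedback_gain``.
    """

    ec50_IAA: float = 0.13
    hill_IAA: float = 2.0
    ec50_SA: float = 407.3
    hill_SA: float = 2.0
    tau_u_h: float = 1.5
    alpha: float = 1.0
    basal_frac: float = 0.02
    reporter_halflife_h: float = 2.5
    mcherry_level: float = 1.0
    growth_dilution_h: float = 0.1
    extrinsic_cv: float = 0.1
    measurement_cv: float = 0.05
    feedback_mode: str = "OL"
    feedback_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50_IAA <= 0 or self.ec50_SA <= 0:
            raise CircuitError("EC50 values must be positive")
        if self.hill_IAA < 1 or self.hill_SA < 1:
            raise CircuitError("Hill coefficients must be >= 1")
        if self.reporter_halflife_h <= 0:
            raise CircuitError("reporter_halflife_h must be positive")
        if not (0 <= self.basal_frac < 1):
            raise CircuitError("basal_frac must lie in [0, 1)")
        if not (0 <= self.extrinsic_cv <= 0.5):
            raise CircuitError("extrinsic_cv must lie in [0, 0.5]")
        if self.measurement_cv < 0:
            raise CircuitError("measurement_cv must be >= 0")
        if self.tau_u_h < 0:
            raise CircuitError("tau_u_h must be >= 0")
        if self.feedback_mode not in ("OL", "NFL", "PFL"):
            raise CircuitError(
                f"feedback_mode must be one of OL/NFL/PFL, got {self.feedback_mode!r}"
            )
        if self.feedback_gain < 0:
            raise CircuitError("feedback_gain must be >= 0")

    @property
    def decay_rate_h(self) -> float:
        """Total reporter removal rate: degradation plus growth dilution (1/h)."""
        return np.log(2.0) / self.reporter_halflife_h + self.growth_dilution_h

    @property
    def g_ref(self) -> float:
        """Reference reporter level used by the feedback scalings."""
        return self.alpha * self.reporter_halflife_h / np.log(2.0)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _hill(c: np.ndarray, ec50: float, n: float) -> np.ndarray:
    cn = np.power(c, n)
    return cn / (cn + ec50**n)


def chemical_to_drive(
    c_SA: np.ndarray,
    c_IAA: np.ndarray,
    params: CircuitParams,
    dt_h: float,
) -> np.ndarray:
    """Effective drive u(t) in [-1, 1] from the two concentration waveforms.

    ``u_raw = Hill_IAA(c_IAA) - Hill_SA(c_SA)`` relaxed through
    ``du/dt = (u_raw - u)/tau_u_h`` with ``u(0) = u_raw(0)``.  The relaxation
    uses the exact exponential update for input held constant over each
    step, so a step input reaches ``1 - 1/e`` of its asymptote exactly one
    time constant after the step.
    """
    c_SA = np.asarray(c_SA, dtype=float)
    c_IAA = np.asarray(c_IAA, dtype=float)
    if c_SA.shape != c_IAA.shape:
        raise CircuitError("concentration waveforms must share a grid")
    if c_SA.size == 0:
        raise CircuitError("empty concentration grid")
    if np.any(c_SA < 0) or np.any(c_IAA < 0):
        raise CircuitError("negative concentrations")
    u_raw = _hill(c_IAA, params.ec50_IAA, params.hill_IAA) - _hill(
        c_SA, params.ec50_SA, params.hill_SA
    )
    if params.tau_u_h == 0.0:
        return u_raw
    d = np.exp(-dt_h / params.tau_u_h)
    u = np.empty_like(u_raw)
    u[0] = u_raw[0]
    # u[k] = u_raw[k-1] + (u[k-1] - u_raw[k-1]) * d  (input held over the step)
    from scipy.signal import lfilter

    if u_raw.size > 1:
        u[1:] = lfilter([1.0 - d], [1.0, -d], u_raw[:-1], zi=np.asarray([d * u_raw[0]]))[0]
    return u
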