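"""Hill dose-response machinery: receptor response kinetics and EC50 fits.

The receptor modules follow a four-parameter logistic (Hill) curve

    R(c) = bottom + (top - bottom) * c^n / (c^n + EC50^n),

fit by least squares with the EC50 parametrized on the log scale (so the
optimizer cannot wander into non-positive concentrations and the standard
error transforms cleanly).  Zero-concentration points enter through the
untransformed model; no logarithm of zero is ever taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["HillFit", "HillFitError", "hill_response", "fit_hill"]


class HillFitError(RuntimeError):
    """The dose-response data do not support a Hill fit."""


@dataclass(frozen=True)
class HillFit:
    bottom: float
    top: float
    ec50: float
    hill_n: float
    rss: float = 0.0
    se_ec50: float = float("nan")

    def __post_init__(self) -> None:
        if self.top <= self.bottom:
            raise HillFitError("top must exceed bottom")
        if self.ec50 <= 0:
            raise HillFitError("ec50 must be positive")
        if self.hill_n <= 0:
            raise HillFitError("hill_n must be positive")

    def ec50_ci95(self) -> Tuple[float, float]:
        """95% confidence interval for the EC50 (log-scale Wald interval)."""
        se_log = self.se_ec50 / self.ec50
        return (
            self.ec50 * np.exp(-1.959963984540054 * se_log),
            self.ec50 * np.exp(+1.959963984540054 * se_log),
        )

    def to_dict(self) -> dict:
        return {
            "bottom": self.bottom,
            "top": self.top,
            "ec50": self.ec50,
            "hill_n": self.hill_n,
            "rss": self.rss,
            "se_ec50": self.se_ec50,
        }


def _hill(c, bottom, top, log_ec50, n):
    c = np.asarray(c, dtype=float)
    ec50 = np.exp(log_ec50)
    cn = np.power(c, n)
    return bottom + (top - bottom) * cn / (cn + ec50**n)


def hill_response(c, fit: HillFit):
    """Evaluate the fitted curve; monotone non-decreasing in concentration."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise HillFitError("negative concentration")
    out = _hill(c, fit.bottom, fit.top, np.log(fit.ec50), fit.hill_n)
    return out if out.ndim else float(out)


def fit_hill(
    concentrations: Sequence[float],
    responses: Sequence[float],
) -> HillFit:
    """Least-squares 4-parameter Hill fit of pooled dose-response data.

    ``concentrations`` and ``responses`` are aligned vectors; replicates
    appear as repeated concentrations.  Initialization from the data:
    bottom = min, top = max, EC50 = geometric middle of the positive
    concentration range, n = 1.  Raises :class:`HillFitError` for flat or
    non-informative data (fitted dynamic range below three residual
    standard deviations), instead of returning a silent bad fit.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise HillFitError("concentrations and responses must be aligned vectors")
    if np.any(c < 0):
        raise HillFitError("negative concentration")
    if np.any(y < 0):
        raise HillFitError("responses must be non-negative")
    if len(np.unique(c)) < 4:
        raise HillFitError("need at least 4 distinct concentrations")
    if np.ptp(y) == 0:
        raise HillFitError("responses are constant; no transition to fit")
    pos = c[c > 0]
    log_mid = 0.5 * (np.log(pos.min()) + np.log(pos.max()))
    p0 = [float(y.min()), float(y.max()), float(log_mid), 1.0]
    bounds = (
        [-np.inf, -np.inf, np.log(pos.min()) - 10.0, 1e-3],
        [np.inf, np.inf, np.log(pos.max()) + 10.0, 50.0],
    )
    try:
        popt, pcov = curve_fit(_hill, c, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise HillFitError(f"Hill fit did not converge: {exc}") from exc
    bottom, top, log_ec50, n = popt
    resid = y - _hill(c, *popt)
    rss = float(np.sum(resid**2))
    dof = max(len(y) - 4, 1)
    resid_sd = np.sqrt(rss / dof)
    if top - bottom <= 0:
        raise HillFitError("fitted dynamic range is non-positive")
    if resid_sd > 0 and (top - bottom) < 3.0 * resid_sd:
        raise HillFitError(
            "fitted dynamic range below 3x residual SD; data are flat or "
            "non-monotone"
        )
    se_log = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
    ec50 = float(np.exp(log_ec50))
    return HillFit(
        bottom=float(bottom),
        top=float(top),
        ec50=ec50,
        hill_n=float(n),
        rss=rss,
        se_ec50=ec50 * se_log,
    )
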