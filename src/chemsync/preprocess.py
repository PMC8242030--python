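"""Trace conditioning: growth normalization, detrending, smoothing, rescaling.

The canonical order, applied column-wise per community, is

    normalize_growth -> detrend_linear -> smooth_savgol -> rescale01,

mirroring the analysis of the microfluidics recordings: the constitutive
mCherry marker corrects for growth (dEGFP/(dEGFP+mCherry)), a least-squares
line removes slow drift, a Savitzky-Golay filter of length 15 smooths the
10-min samples, and the 0-1 rescaling feeds the heatmaps.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import detrend as _scipy_detrend
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessError",
    "normalize_growth",
    "detrend_linear",
    "smooth_savgol",
    "rescale01",
    "preprocess_matrix",
]


class PreprocessError(ValueError):
    pass


def normalize_growth(degfp: np.ndarray, mcherry: np.ndarray) -> np.ndarray:
    """Growth-corrected signal dEGFP/(dEGFP + mCherry), in [0, 1].

    Points where both channels read zero (dead or empty ROIs) are defined
    as 0: no growth marker and no reporter means no signal.
    """
    g = np.asarray(degfp, dtype=float)
    m = np.asarray(mcherry, dtype=float)
    if g.shape != m.shape:
        raise PreprocessError(f"shape mismatch: {g.shape} vs {m.shape}")
    if np.any(g < 0) or np.any(m < 0):
        raise PreprocessError("negative fluorescence values")
    total = g + m
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, g / np.where(total > 0, total, 1.0), 0.0)
    return out


def detrend_linear(trace: np.ndarray, axis: int = 0) -> np.ndarray:
    """Subtract the least-squares straight line (zero mean, zero slope out)."""
    x = np.asarray(trace, dtype=float)
    if x.shape[axis] < 3:
        raise PreprocessError("need at least 3 samples to detrend")
    return _scipy_detrend(x, axis=axis, type="linear")


def smooth_savgol(trace: np.ndarray, window: int = 15, polyorder: int = 3, axis: int = 0) -> np.ndarray:
    """Savitzky-Golay smoothing (filter length 15, cubic by default).

    Boundaries are handled by polynomial fits on the leading/trailing
    window (no wrap-around), so bursts near the record edges do not alias.
    Polynomials of degree <= ``polyorder`` pass through unchanged.
    """
    x = np.asarray(trace, dtype=float)
    if window % 2 == 0:
        raise PreprocessError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise PreprocessError("window must exceed polyorder")
    if x.shape[axis] < window:
        raise PreprocessError(
            f"trace length {x.shape[axis]} shorter than window {window}"
        )
    return savgol_filter(x, window_length=window, polyorder=polyorder, axis=axis, mode="interp")


def rescale01(trace: np.ndarray, axis: int = 0) -> np.ndarray:
    """Affine map of each column onto [0, 1]; min -> 0, max -> 1.

    A constant trace has no range and raises: the caller decides what a
    flat community means.
    """
    x = np.asarray(trace, dtype=float)
    lo = x.min(axis=axis, keepdims=True)
    hi = x.max(axis=axis, keepdims=True)
    if np.any(hi - lo == 0):
        raise PreprocessError("constant trace cannot be rescaled to [0, 1]")
    return (x - lo) / (hi - lo)


def preprocess_matrix(
    degfp: np.ndarray,
    mcherry: np.ndarray,
    window: int = 15,
    polyorder: int = 3,
) -> np.ndarray:
    """Full conditioning chain on (time x community) matrices."""
    x = normalize_growth(degfp, mcherry)
    x = detrend_linear(x)
    x = smooth_savgol(x, window=window, polyorder=polyorder)
    return rescale01(x)
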