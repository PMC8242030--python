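"""Quantification of oscillatory reporter traces.

Implements the measurements used on the microfluidics recordings: burst
detection with the nups/ndowns rule, periods as distances between
successive peaks, the response-precision index, inter-community phase
drift, a synchronization fraction, cumulative (ensemble-averaged)
autocorrelation, power spectral density with dominant period, and
period-doubling ratios against the chemical rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import peak_prominences, peak_widths
from statsmodels.tsa.stattools import acf as _sm_acf

from .programs import InputProgram

__all__ = [
    "PeakSet",
    "MetricsReport",
    "MetricsError",
    "find_peaks",
    "find_peaks_matrix",
    "compute_periods",
    "response_precision",
    "phase_drift",
    "sync_fraction",
    "cumulative_acf",
    "power_spectrum",
    "doubling_ratios",
    "compute_metrics",
]

SNAP_LEVELS = (1.0, 2.0, 4.0, 8.0)


class MetricsError(ValueError):
    pass


@dataclass
class PeakSet:
    """Peaks of one community's trace."""

    peak_times_min: np.ndarray
    peak_heights: np.ndarray
    prominences: np.ndarray
    fwhp_min: np.ndarray  # full width at half prominence

    def __post_init__(self) -> None:
        self.peak_times_min = np.asarray(self.peak_times_min, dtype=float)
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)
        self.prominences = np.asarray(self.prominences, dtype=float)
        self.fwhp_min = np.asarray(self.fwhp_min, dtype=float)
        if np.any(np.diff(self.peak_times_min) <= 0):
            raise MetricsError("peak times must be strictly increasing")
        n = len(self.peak_times_min)
        if not (len(self.peak_heights) == len(self.prominences) == len(self.fwhp_min) == n):
            raise MetricsError("per-peak arrays must have equal length")
        if n and np.any(self.fwhp_min <= 0):
            raise MetricsError("peak widths must be positive")

    def __len__(self) -> int:
        return len(self.peak_times_min)


def find_peaks(
    trace: np.ndarray,
    time_min: np.ndarray | None = None,
    nups: int = 6,
    ndowns: int = 6,
    min_prominence: float = 0.0,
) -> PeakSet:
    """Burst detection with the nups/ndowns rule.

    Index ``i`` is a peak iff it is preceded by at least ``nups``
    non-decreasing steps (the step into the apex strictly rising), followed
    by at least ``ndowns`` non-increasing steps (the step off the apex
    strictly falling), and its prominence is at least ``min_prominence``.
    The full width at half prominence is measured at height
    ``peak - prominence/2`` by linear interpolation between samples.
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < nups + ndowns + 1:
        raise MetricsError(
            f"trace of length {n} shorter than nups+ndowns+1 = {nups + ndowns + 1}"
        )
    if time_min is None:
        time_min = np.arange(n, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    dt = time_min[1] - time_min[0] if n > 1 else 1.0
    d = np.diff(x)
    up = (d >= 0).astype(int)
    down = (d <= 0).astype(int)
    # up_run[j] == nups  <=>  d[j : j+nups] are all non-decreasing steps
    up_run = np.convolve(up, np.ones(nups, dtype=int), mode="valid")
    down_run = np.convolve(down, np.ones(ndowns, dtype=int), mode="valid")
    idx = []
    for i in range(nups, n - ndowns):
        if d[i - 1] > 0 and d[i] < 0 and up_run[i - nups] == nups and down_run[i] == ndowns:
            idx.append(i)
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        empty = np.empty(0)
        return PeakSet(empty, empty, empty, empty)
    prom, lb, rb = peak_prominences(x, idx)
    keep = prom >= min_prominence
    idx, prom, lb, rb = idx[keep], prom[keep], lb[keep], rb[keep]
    if idx.size == 0:
        empty = np.empty(0)
        return PeakSet(empty, empty, empty, empty)
    widths, _, _, _ = peak_widths(x, idx, rel_height=0.5, prominence_data=(prom, lb, rb))
    return PeakSet(
        peak_times_min=time_min[idx],
        peak_heights=x[idx],
        prominences=prom,
        fwhp_min=widths * dt,
    )


def find_peaks_matrix(
    matrix: np.ndarray,
    time_min: np.ndarray,
    nups: int = 6,
    ndowns: int = 6,
    min_prominence: float = 0.0,
) -> List[PeakSet]:
    return [
        find_peaks(matrix[:, j], time_min, nups, ndowns, min_prominence)
        for j in range(matrix.shape[1])
    ]


def compute_periods(peaks: PeakSet) -> np.ndarray:
    """First differences of peak times, in hours; empty with < 2 peaks."""
    if len(peaks) < 2:
        return np.empty(0)
    return np.diff(peaks.peak_times_min) / 60.0


def response_precision(width_output_min: float, width_input_min: float) -> float:
    """Relative agreement between burst width and input pulse width.

    ``1 - |w_out - w_in| / (w_out + w_in)``: lies in (0, 1], equals 1 iff
    the widths match.  The absolute difference keeps the index bounded by 1
    also when the output is narrower than the input.
    """
    if width_output_min <= 0 or width_input_min <= 0:
        raise MetricsError("widths must be positive")
    return 1.0 - abs(width_output_min - width_input_min) / (
        width_output_min + width_input_min
    )


def _assign_to_cycles(peaks: PeakSet, program: InputProgram) -> np.ndarray:
    """Per cycle, the peak time nearest the cycle's drive onset (NaN if none
    within half a period)."""
    T = 60.0 * program.period_h
    out = np.full(program.n_cycles, np.nan)
    t = peaks.peak_times_min
    if len(t) == 0:
        return out
    for k in range(program.n_cycles):
        onset = k * T
        dist = np.abs(t - onset)
        j = int(np.argmin(dist))
        if dist[j] <= T / 2.0:
            out[k] = t[j]
    return out


def phase_drift(peaksets: Sequence[PeakSet], program: InputProgram) -> float:
    """Inter-community phase drift, % of the input period.

    For each cycle, each community contributes the peak nearest the cycle's
    drive onset (within half a period); the drift of that cycle is the
    standard deviation of those peak times across communities, as a
    percentage of the period.  The reported value is the mean over cycles
    with at least two assignments.
    """
    if len(peaksets) < 2:
        raise MetricsError("need at least two communities")
    T = 60.0 * program.period_h
    assigned = np.vstack([_assign_to_cycles(p, program) for p in peaksets])
    drifts = []
    for k in range(assigned.shape[1]):
        col = assigned[:, k]
        col = col[np.isfinite(col)]
        if len(col) >= 2:
            drifts.append(np.std(col, ddof=1) / T * 100.0)
    if not drifts:
        raise MetricsError("no cycle has two or more assigned peaks")
    return float(np.mean(drifts))


def sync_fraction(
    peaksets: Sequence[PeakSet],
    program: InputProgram,
    lag_tol_min: Optional[float] = None,
    cycle_coverage: float = 0.9,
) -> float:
    """Fraction of communities locked to the rhythm, in [0, 1].

    The cycle reference is the drive onset shifted by the ensemble median
    peak lag (so the systematic activation delay of the circuit does not
    count against locking).  Only cycle windows lying entirely inside the
    record are scored.  A community is locked when it shows exactly one
    peak in at least ``cycle_coverage`` of those windows and its mean
    distance from the reference stays below ``lag_tol_min`` (default T/4).
    """
    if len(peaksets) < 2:
        raise MetricsError("need at least two communities")
    T = 60.0 * program.period_h
    if lag_tol_min is None:
        lag_tol_min = T / 4.0
    n_cycles = program.n_cycles
    assigned = np.vstack([_assign_to_cycles(p, program) for p in peaksets])
    onsets = np.arange(n_cycles) * T
    lags = assigned - onsets[None, :]
    lags = lags[np.isfinite(lags)]
    if lags.size == 0:
        return 0.0
    L = float(np.median(lags))
    duration_min = 60.0 * program.duration_h
    refs = onsets + L
    refs = refs[(refs - T / 2.0 >= 0.0) & (refs + T / 2.0 <= duration_min)]
    if refs.size == 0:
        return 0.0
    n_locked = 0
    for p in peaksets:
        t = p.peak_times_min
        good = 0
        devs = []
        for ref in refs:
            in_win = t[(t >= ref - T / 2.0) & (t < ref + T / 2.0)]
            if len(in_win) == 1:
                good += 1
                devs.append(abs(in_win[0] - ref))
        if good >= cycle_coverage * len(refs) and devs and np.mean(devs) < lag_tol_min:
            n_locked += 1
    return n_locked / len(peaksets)


def cumulative_acf(
    matrix: np.ndarray,
    time_min: np.ndarray,
    max_lag_h: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Ensemble-averaged sample autocorrelation of (detrended) traces.

    Per community the biased estimator (normalized by N, acf(0)=1) is used,
    then averaged across communities.  Returns (lag_h, acf).
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[0] == 1:
        matrix = matrix.T
    dt_h = (time_min[1] - time_min[0]) / 60.0
    duration_h = len(time_min) * dt_h
    if max_lag_h is None:
        max_lag_h = duration_h / 2.0
    if max_lag_h >= duration_h:
        raise MetricsError("max lag must be shorter than the record")
    nlags = int(round(max_lag_h / dt_h))
    vals = np.column_stack(
        [_sm_acf(matrix[:, j], nlags=nlags, adjusted=False, fft=True) for j in range(matrix.shape[1])]
    )
    return np.arange(nlags + 1) * dt_h, vals.mean(axis=1)


def power_spectrum(
    matrix: np.ndarray,
    time_min: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Periodogram of the ensemble-mean trace (no window, 4x zero-padding).

    Power is normalized so that its sum equals the variance of the mean
    trace (Parseval).  Returns (freq_per_h, power, dominant_period_h); the
    dominant period excludes the zero-frequency bin.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[0] == 1:
        matrix = matrix.T
    x = matrix.mean(axis=1)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise MetricsError("constant input has no spectrum")
    n = x.size
    m = 4 * n
    dt_h = (time_min[1] - time_min[0]) / 60.0
    spec = np.fft.rfft(x, m)
    power = np.abs(spec) ** 2 / (m * n)
    # one-sided: double everything except DC (and Nyquist when m is even)
    power[1:] *= 2.0
    if m % 2 == 0:
        power[-1] /= 2.0
    freq = np.fft.rfftfreq(m, d=dt_h)
    k = int(np.argmax(power[1:])) + 1
    dominant_period_h = 1.0 / freq[k]
    return freq, power, float(dominant_period_h)


def doubling_ratios(
    peaksets: Sequence[PeakSet],
    program: InputProgram,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per community, median response period over the input period.

    Returns ``(raw, snapped)``: the raw ratio, and the value snapped to the
    nearest of {1, 2, 4, 8} when within 25% relative distance (NaN when no
    level is that close).  Communities with fewer than two peaks are
    omitted.
    """
    raws = []
    for p in peaksets:
        periods = compute_periods(p)
        if periods.size == 0:
            continue
        raws.append(float(np.median(periods)) / program.period_h)
    raw = np.asarray(raws)
    snapped = np.full(raw.shape, np.nan)
    for i, r in enumerate(raw):
        best = min(SNAP_LEVELS, key=lambda s: abs(r - s) / s)
        if abs(r - best) / best <= 0.25:
            snapped[i] = best
    return raw, snapped


@dataclass
class MetricsReport:
    """Ensemble statistics of one recording."""

    precision_per_trap: List[float]
    periods_h: List[float]
    amplitudes: List[float]
    phase_drift_pct: float
    sync_fraction: float
    acf_lag_h: List[float]
    acf: List[float]
    psd_freq_per_h: List[float]
    psd_power: List[float]
    dominant_period_h: float
    doubling_ratios_raw: List[float]
    doubling_ratios_snapped: List[float]

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and not np.isfinite(v):
                return None
            return v

        return {
            "precision_per_trap": [clean(float(v)) for v in self.precision_per_trap],
            "periods_h": [float(v) for v in self.periods_h],
            "amplitudes": [float(v) for v in self.amplitudes],
            "phase_drift_pct": clean(float(self.phase_drift_pct)),
            "sync_fraction": float(self.sync_fraction),
            "acf_lag_h": [float(v) for v in self.acf_lag_h],
            "acf": [float(v) for v in self.acf],
            "psd_freq_per_h": [float(v) for v in self.psd_freq_per_h],
            "psd_power": [float(v) for v in self.psd_power],
            "dominant_period_h": float(self.dominant_period_h),
            "doubling_ratios_raw": [float(v) for v in self.doubling_ratios_raw],
            "doubling_ratios_snapped": [clean(float(v)) for v in self.doubling_ratios_snapped],
        }


def compute_metrics(
    matrix: np.ndarray,
    time_min: np.ndarray,
    program: InputProgram,
    nups: int = 6,
    ndowns: int = 6,
    min_prominence: float = 0.1,
    lag_tol_min: Optional[float] = None,
    cycle_coverage: float = 0.9,
) -> MetricsReport:
    """All trace metrics on a conditioned (time x community) matrix.

    The matrix is expected to be growth-normalized, detrended, smoothed and
    rescaled (see :mod:`chemsync.preprocess`); ``min_prominence`` is on the
    0-1 scale of the rescaled traces.
    """
    peaksets = find_peaks_matrix(matrix, time_min, nups, ndowns, min_prominence)
    width_in = 60.0 * program.pulse_width_h
    precision = []
    for p in peaksets:
        if len(p) == 0:
            precision.append(np.nan)
        else:
            precision.append(response_precision(float(np.median(p.fwhp_min)), width_in))
    periods = np.concatenate([compute_periods(p) for p in peaksets]) if peaksets else np.empty(0)
    amplitudes = np.concatenate([p.peak_heights for p in peaksets]) if peaksets else np.empty(0)
    try:
        drift = phase_drift(peaksets, program)
    except MetricsError:
        drift = float("nan")
    sync = sync_fraction(peaksets, program, lag_tol_min, cycle_coverage)
    lag_h, acf_vals = cumulative_acf(matrix, time_min)
    freq, power, dom = power_spectrum(matrix, time_min)
    raw, snapped = doubling_ratios(peaksets, program)
    return MetricsReport(
        precision_per_trap=list(precision),
        periods_h=list(periods),
        amplitudes=list(amplitudes),
        phase_drift_pct=drift,
        sync_fraction=sync,
        acf_lag_h=list(lag_h),
        acf=list(acf_vals),
        psd_freq_per_h=list(freq),
        psd_power=list(power),
        dominant_period_h=dom,
        doubling_ratios_raw=list(raw),
        doubling_ratios_snapped=list(snapped),
    )
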