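"""Noisy bistable switch with rate-dependent hysteresis.

The promoter is modelled as a two-state Schmitt trigger: it turns ON when
the effective drive plus Ornstein-Uhlenbeck noise exceeds ``theta_on`` and
OFF when it falls below ``theta_off``.  The separation of the two thresholds
(the hysteresis width) is not fixed but grows with the rate of the chemical
rhythm,

    h(T) = h0 * (1 + kappa * T_ref / T),

so fast rhythms see a wide loop that rejects noise while slow rhythms see a
narrow one.  This is the rate-dependent-hysteresis picture familiar from
piezoelectric actuator control, transplanted to a noisy gene switch driven
near the stochastic-resonance regime.

Discrete states make every downstream metric exactly computable and give a
trivial noiseless oracle (an exhaustive threshold-crossing scan).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .programs import InputProgram

__all__ = [
    "SwitchParams",
    "SwitchTrajectory",
    "SwitchError",
    "hysteresis_width",
    "thresholds",
    "simulate_switch",
    "sync_index",
    "sweep_noise_rate",
]


class SwitchError(ValueError):
    """Invalid switch parameters or drive."""


@dataclass(frozen=True)
class SwitchParams:
    """Parameters of the hysteretic switch.

    ``mid`` is the threshold midpoint on the drive axis (drive is the Hill
    difference of the two receptor occupancies, bounded in [-1, 1]); ``h0``
    the base hysteresis width at very slow driving; ``kappa`` the
    rate-dependence coefficient referenced to ``T_ref_h``; ``noise_sigma``
    and ``noise_tau_h`` the stationary standard deviation and correlation
    time of the OU noise added to the drive; ``dt_h`` the integration step.

    Defaults were calibrated once against the drive mapping so that the
    deterministic drive clears both thresholds at 4-10 h rhythms, a fast
    (2 h) rhythm pushes ``theta_off`` below zero (an IAA-only rhythm can
    then never switch OFF), and a slow single pulse still releases the
    switch with an hour-scale lag.
    """

    mid: float = 0.2
    h0: float = 0.1
    kappa: float = 1.25
    T_ref_h: float = 10.0
    noise_sigma: float = 0.1
    noise_tau_h: float = 0.5
    dt_h: float = 1.0 / 120.0

    def __post_init__(self) -> None:
        if self.h0 < 0:
            raise SwitchError("h0 must be >= 0")
        if self.kappa < 0:
            raise SwitchError("kappa must be >= 0")
        if self.T_ref_h <= 0 or self.dt_h <= 0 or self.noise_tau_h <= 0:
            raise SwitchError("T_ref_h, dt_h and noise_tau_h must be positive")
        if self.noise_sigma < 0:
            raise SwitchError("noise_sigma must be >= 0")
        if self.noise_sigma > 0 and self.dt_h > self.noise_tau_h / 5.0:
            raise SwitchError(
                f"dt_h={self.dt_h} too coarse for noise_tau_h={self.noise_tau_h}; "
                "require dt_h <= noise_tau_h/5"
            )


@dataclass
class SwitchTrajectory:
    """A realization of the switch: binary promoter state on a time grid."""

    time_h: np.ndarray
    state: np.ndarray  # {0,1}
    drive: np.ndarray
    thresholds: Tuple[float, float]  # (theta_on, theta_off)

    def on_transition_times(self) -> np.ndarray:
        """Times of 0->1 transitions (the sample at which the state is first ON)."""
        s = self.state
        # an initial ON state is not a transition
        idx = np.flatnonzero((s[1:] == 1) & (s[:-1] == 0)) + 1
        return self.time_h[idx]


def hysteresis_width(T_input_h: float, params: SwitchParams) -> float:
    """Effective hysteresis width for a rhythm of period ``T_input_h``.

    ``h = h0 * (1 + kappa * T_ref / T)``: strictly decreasing in the period
    when ``kappa > 0`` and equal to ``h0*(1+kappa)`` at the reference period.
    """
    if T_input_h <= 0:
        raise SwitchError(f"input period must be positive, got {T_input_h}")
    return params.h0 * (1.0 + params.kappa * params.T_ref_h / T_input_h)


def thresholds(params: SwitchParams, period_h: float | None = None) -> Tuple[float, float]:
    """(theta_on, theta_off) for a given driving period (base width if None)."""
    h = params.h0 if period_h is None else hysteresis_width(period_h, params)
    return params.mid + h / 2.0, params.mid - h / 2.0


def _ou_noise(n: int, params: SwitchParams, rng: np.random.Generator) -> np.ndarray:
    """Stationary OU noise via the Euler-Maruyama recursion.

    eta[k+1] = eta[k]*(1 - dt/tau) + sigma*sqrt(2 dt/tau) * N(0,1), with
    eta[0] drawn from the exact stationary distribution of the recursion.
    """
    if params.noise_sigma == 0.0:
        return np.zeros(n)
    a = 1.0 - params.dt_h / params.noise_tau_h
    b = params.noise_sigma * np.sqrt(2.0 * params.dt_h / params.noise_tau_h)
    sd0 = b / np.sqrt(1.0 - a * a)
    eta0 = rng.normal(0.0, sd0)
    w = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    # eta[k] = a*eta[k-1] + b*w[k-1]  -> linear filter with initial condition
    eta = np.empty(n)
    eta[0] = eta0
    if n > 1:
        eta[1:] = lfilter([b], [1.0, -a], w, zi=np.asarray([a * eta0]))[0]
    return eta


def schmitt_states(x: np.ndarray, s0: int, th_on: float, th_off: float) -> np.ndarray:
    """Exact vectorized Schmitt trigger on a sampled signal.

    The hysteretic state at sample k equals the outcome of the most recent
    decisive excursion (strictly above ``th_on`` -> 1, strictly below
    ``th_off`` -> 0), or the initial state if none has occurred yet, which
    is a forward fill over the excursion markers.
    """
    n = x.size
    marker = np.full(n, -1, dtype=np.int64)
    decisive = np.flatnonzero((x > th_on) | (x < th_off))
    marker[decisive] = decisive
    last = np.maximum.accumulate(marker)
    state = np.empty(n, dtype=np.uint8)
    none_yet = last < 0
    state[none_yet] = s0
    seen = ~none_yet
    state[seen] = (x[last[seen]] > th_on).astype(np.uint8)
    return state


def simulate_switch(
    u: np.ndarray,
    params: SwitchParams,
    seed: int | np.random.SeedSequence | None,
    period_h: float | None = None,
) -> SwitchTrajectory:
    """Run the Schmitt trigger on a uniformly sampled drive.

    ``u`` is sampled at ``params.dt_h``.  The initial state is the indicator
    ``u[0] > mid``; afterwards the state flips 0->1 when ``u + eta`` strictly
    exceeds ``theta_on`` and 1->0 when it falls strictly below ``theta_off``
    (a value landing exactly on a threshold does not flip).  ``period_h``
    selects the rate-dependent width; without it the base width ``h0`` is
    used.  Identical seed implies an identical trajectory.
    """
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise SwitchError("empty drive")
    if not np.all(np.isfinite(u)):
        raise SwitchError("drive contains non-finite values")
    th_on, th_off = thresholds(params, period_h)
    rng = np.random.default_rng(seed)
    eta = _ou_noise(u.size, params, rng)
    x = u + eta
    s0 = 1 if u[0] > params.mid else 0
    state = schmitt_states(x, s0, th_on, th_off)
    time_h = np.arange(u.size) * params.dt_h
    return SwitchTrajectory(time_h=time_h, state=state, drive=u, thresholds=(th_on, th_off))


def _cycle_period_duration(program_or_period, duration_h: float | None, time_h: np.ndarray):
    if isinstance(program_or_period, InputProgram):
        T = program_or_period.period_h
        dur = program_or_period.duration_h
    else:
        T = float(program_or_period)
        dur = duration_h if duration_h is not None else float(time_h[-1]) + (
            time_h[1] - time_h[0] if len(time_h) > 1 else 0.0
        )
    return T, dur


def sync_index(
    trajectories: Sequence[SwitchTrajectory],
    program_or_period,
    duration_h: float | None = None,
    mid: float | None = None,
) -> float:
    """Fraction of (trajectory, cycle) pairs locked to the drive.

    A pair counts as locked when the cycle window ``[kT, (k+1)T)`` contains
    exactly one ON transition and that transition lies within ``T/4`` of the
    drive's upward crossing of the threshold midpoint inside the same window.
    Returns a value in [0, 1]; 1 means perfect locking.
    """
    if len(trajectories) < 2:
        raise SwitchError("need at least two trajectories")
    t0 = trajectories[0].time_h
    for tr in trajectories[1:]:
        if tr.time_h.shape != t0.shape or not np.allclose(tr.time_h, t0):
            raise SwitchError("trajectories are on mismatched time grids")
    T, dur = _cycle_period_duration(program_or_period, duration_h, t0)
    n_cycles = int(np.floor(dur / T + 1e-9))
    if n_cycles < 1:
        raise SwitchError("record shorter than one cycle")
    hits = 0
    total = 0
    for tr in trajectories:
        m = tr.thresholds[0] / 2 + tr.thresholds[1] / 2 if mid is None else mid
        d = tr.drive
        up_cross = np.flatnonzero((d[:-1] <= m) & (d[1:] > m)) + 1
        up_times = tr.time_h[up_cross]
        on_times = tr.on_transition_times()
        for k in range(n_cycles):
            lo, hi = k * T, (k + 1) * T
            total += 1
            ons = on_times[(on_times >= lo) & (on_times < hi)]
            if len(ons) != 1:
                continue
            refs = up_times[(up_times >= lo) & (up_times < hi)]
            if len(refs) == 0:
                continue
            if abs(ons[0] - refs[0]) <= T / 4.0:
                hits += 1
    return hits / total


def _square_drive(period_h: float, amplitude: float, n_cycles: int, dt_h: float) -> np.ndarray:
    """Symmetric square drive: -A on the first half-cycle, +A on the second.

    Starting LOW makes the upward crossing (and hence the expected ON
    transition) fall inside every cycle window, including the first.
    """
    n_per = int(round(period_h / dt_h))
    one = np.concatenate(
        [np.full(n_per // 2, -amplitude), np.full(n_per - n_per // 2, amplitude)]
    )
    return np.tile(one, n_cycles)


def sweep_noise_rate(
    noise_grid: Sequence[float],
    period_grid: Sequence[float],
    amplitude: float,
    params: SwitchParams,
    n_rep: int,
    seed: int,
    n_trajectories: int = 10,
    n_cycles: int = 10,
) -> np.ndarray:
    """Mean sync index over a (noise level x driving period) grid.

    Each cell averages :func:`sync_index` of ``n_trajectories`` independent
    switches under an idealized square drive of the given amplitude, over
    ``n_rep`` seeds.  The rate-dependent width (via ``params.kappa``) is
    applied per period.
    """
    noise_grid = list(noise_grid)
    period_grid = list(period_grid)
    if not noise_grid or not period_grid:
        raise SwitchError("grids must be non-empty")
    if n_rep < 1:
        raise SwitchError("n_rep must be >= 1")
    out = np.empty((len(noise_grid), len(period_grid)))
    for i, sigma in enumerate(noise_grid):
        p = replace(params, noise_sigma=float(sigma))
        for j, T in enumerate(period_grid):
            u = _square_drive(T, amplitude, n_cycles, p.dt_h)
            vals = []
            for r in range(n_rep):
                trajs = [
                    simulate_switch(
                        u,
                        p,
                        np.random.SeedSequence(entropy=seed, spawn_key=(i, j, r, c)),
                        period_h=T,
                    )
                    for c in range(n_trajectories)
                ]
                vals.append(
                    sync_index(trajs, T, duration_h=n_cycles * T, mid=params.mid)
                )
            out[i, j] = float(np.mean(vals))
    return out
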