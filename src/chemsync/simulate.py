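"""Simulation of per-community reporter traces.

Each yeast community is an independent realization of the same circuit: the
chemical program is mapped to an effective drive, the drive feeds the noisy
hysteretic switch (:mod:`chemsync.switch`), and the promoter state drives a
short-lived reporter

    dG/dt = alpha_eff * (basal + (1 - basal) * P(t)) - gamma * G,

with ``gamma`` the sum of reporter degradation and growth dilution.
Communities are mutually uncoupled; heterogeneity enters only through
lognormal extrinsic variation of expression amplitudes and independent
noise streams split deterministically from the root seed (community index
as spawn key, so adding communities never perturbs existing ones).

The consortium mode adds a killer strain driven by the same rhythm: its
promoter state produces a shared toxin field X, and sensitive communities
accumulate stress while they are themselves active (``ds/dt = X*P - s``,
1-h relaxation).  A community whose stress exceeds the threshold at a cycle
onset skips the next ``refractory_cycles`` cycles — the mechanism behind
the period-doubled response under pulsatile toxin stress.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .circuit import CircuitParams, chemical_to_drive
from .programs import InputProgram, sample_program
from .switch import SwitchParams, _ou_noise, schmitt_states, simulate_switch, thresholds
from .traces import TraceSet

__all__ = [
    "ToxinParams",
    "CommunityTrace",
    "SimulationError",
    "simulate_community",
    "simulate_ensemble",
    "simulate_consortium",
]


class SimulationError(RuntimeError):
    """Numerical failure during simulation."""


@dataclass(frozen=True)
class ToxinParams:
    """Killer-strain toxin action on sensitive communities.

    ``toxin_rate`` (a.u./h) is produced while the killer promoter is ON;
    the field decays at ``toxin_decay_h`` (1/h).  A sensitive community
    integrates stress with a 1-h relaxation while active and, if stressed
    above ``stress_threshold`` at a cycle onset, stays silent for
    ``refractory_cycles`` input cycles before being re-evaluated.
    """

    toxin_rate: float = 1.0
    toxin_decay_h: float = 0.5
    stress_threshold: float = 0.3
    refractory_cycles: int = 1

    def __post_init__(self) -> None:
        if self.toxin_rate < 0 or self.toxin_decay_h < 0:
            raise ValueError("toxin rates must be >= 0")
        if self.stress_threshold <= 0:
            raise ValueError("stress_threshold must be positive")
        if self.refractory_cycles < 1:
            raise ValueError("refractory_cycles must be an integer >= 1")


@dataclass
class CommunityTrace:
    time_min: np.ndarray
    degfp: np.ndarray
    mcherry: np.ndarray
    promoter_state: np.ndarray


def _steps(program: InputProgram, switch: SwitchParams) -> Tuple[int, int, int]:
    dt_h = switch.dt_h
    per_sample = program.dt_min / 60.0 / dt_h
    if abs(per_sample - round(per_sample)) > 1e-9:
        raise SimulationError(
            f"switch dt_h={dt_h} h does not divide the sampling step "
            f"{program.dt_min} min"
        )
    per_cycle = program.period_h / dt_h
    n = int(round(program.duration_h / dt_h))
    return n, int(round(per_sample)), int(round(per_cycle))


def _g_init(circuit: CircuitParams) -> float:
    """Pre-stimulus steady state of the reporter at basal production."""
    g = circuit.alpha * circuit.basal_frac / circuit.decay_rate_h
    for _ in range(100):
        g = _alpha_eff(circuit, g) * circuit.basal_frac / circuit.decay_rate_h
    return g


def _alpha_eff(circuit: CircuitParams, g: float) -> float:
    if circuit.feedback_mode == "OL" or circuit.feedback_gain == 0.0:
        return circuit.alpha
    ratio = g / circuit.g_ref if circuit.g_ref > 0 else 0.0
    if circuit.feedback_mode == "NFL":
        return circuit.alpha / (1.0 + circuit.feedback_gain * ratio)
    # PFL
    return circuit.alpha * (1.0 + circuit.feedback_gain * ratio) / (1.0 + ratio)


def _simulate_core(
    program: InputProgram,
    circuit: CircuitParams,
    switch: SwitchParams,
    seed_seq: np.random.SeedSequence,
    toxin: Optional[ToxinParams] = None,
    toxin_field: Optional[np.ndarray] = None,
) -> CommunityTrace:
    """One community on the internal integration grid.

    The same routine serves the plain ensemble (``toxin=None``) and the
    consortium sensitives, so the toxin-free consortium reduces to the
    ensemble exactly, stream for stream.
    """
    n, per_sample, per_cycle = _steps(program, switch)
    dt = switch.dt_h
    noise_seed, meas_seed = seed_seq.spawn(2)
    _, c_sa, c_iaa = sample_program(program, dt_min=dt * 60.0)
    u = chemical_to_drive(c_sa, c_iaa, circuit, dt)
    th_on, th_off = thresholds(switch, period_h=program.period_h)
    eta = _ou_noise(n, switch, np.random.default_rng(noise_seed))
    x = u + eta

    gamma = circuit.decay_rate_h
    basal = circuit.basal_frac
    mode = circuit.feedback_mode
    gain = circuit.feedback_gain
    alpha = circuit.alpha
    g_ref = circuit.g_ref
    plain = mode == "OL" or gain == 0.0

    g0 = _g_init(circuit)
    s0 = 1 if u[0] > switch.mid else 0
    if toxin is None:
        state = schmitt_states(x, s0, th_on, th_off)
    else:
        # the refractory hold couples the state to the stress history, so
        # this path stays sequential
        state = np.empty(n, dtype=np.uint8)
        s = s0
        stress = 0.0
        refractory_until = -1
        thr = toxin.stress_threshold
        for k in range(n):
            if k % per_cycle == 0 and k >= refractory_until and stress > thr:
                refractory_until = k + toxin.refractory_cycles * per_cycle
            if k < refractory_until:
                s = 0
            else:
                xk = x[k]
                if s == 0:
                    if xk > th_on:
                        s = 1
                elif xk < th_off:
                    s = 0
            state[k] = s
            stress += dt * (toxin_field[k] * s - stress)
    prod = basal + (1.0 - basal) * state.astype(float)
    if plain:
        # G[k] = (1 - gamma dt) G[k-1] + dt * alpha * prod[k]
        from scipy.signal import lfilter

        a = 1.0 - gamma * dt
        G = lfilter([dt * alpha], [1.0, -a], prod, zi=np.asarray([a * g0]))[0]
    else:
        G = np.empty(n)
        g = g0
        for k in range(n):
            if mode == "NFL":
                aeff = alpha / (1.0 + gain * g / g_ref)
            else:
                aeff = alpha * (1.0 + gain * g / g_ref) / (1.0 + g / g_ref)
            g = g + dt * (aeff * prod[k] - gamma * g)
            G[k] = g
    if not np.all(np.isfinite(G)):
        step = int(np.flatnonzero(~np.isfinite(G))[0])
        raise SimulationError(
            f"non-finite reporter state at internal step {step} "
            f"(t={step * dt:.3f} h); check parameters"
        )
    # sample at the imaging cadence
    t_min = np.arange(n // per_sample) * program.dt_min
    degfp = np.maximum(G[::per_sample], 0.0)
    p_sampled = state[::per_sample]
    rng_meas = np.random.default_rng(meas_seed)
    cv = circuit.measurement_cv
    if cv > 0:
        sig = np.sqrt(np.log1p(cv * cv))
        factors = np.exp(rng_meas.normal(-0.5 * sig * sig, sig, size=len(t_min)))
    else:
        factors = np.ones(len(t_min))
    mcherry = circuit.mcherry_level * factors
    return CommunityTrace(time_min=t_min, degfp=degfp, mcherry=mcherry, promoter_state=p_sampled)


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if seed is None:
        raise ValueError("an explicit seed is required")
    return np.random.SeedSequence(seed)


def simulate_community(
    program: InputProgram,
    circuit: CircuitParams,
    switch: SwitchParams,
    seed,
) -> CommunityTrace:
    """Simulate a single community at the nominal parameters."""
    return _simulate_core(program, circuit, switch, _as_seedseq(seed))


def _community_params(
    circuit: CircuitParams, rng: np.random.Generator
) -> CircuitParams:
    """Lognormal (mean-preserving) extrinsic draw of the expression amplitudes."""
    cv = circuit.extrinsic_cv
    if cv == 0.0:
        return circuit
    sig = np.sqrt(np.log1p(cv * cv))
    draw = lambda nominal: nominal * np.exp(rng.normal(-0.5 * sig * sig, sig))
    return replace(circuit, alpha=draw(circuit.alpha), mcherry_level=draw(circuit.mcherry_level))


def _params_hash(program: InputProgram, circuit: CircuitParams, switch: SwitchParams) -> str:
    from dataclasses import asdict

    blob = json.dumps(
        {"program": program.to_dict(), "circuit": asdict(circuit), "switch": asdict(switch)},
        sort_keys=True,
    )
    return hashlib.md5(blob.encode()).hexdigest()


def simulate_ensemble(
    n_communities: int,
    program: InputProgram,
    circuit: CircuitParams,
    switch: SwitchParams,
    seed: int,
) -> TraceSet:
    """Simulate ``n_communities`` mutually uncoupled communities.

    Per-community parameters and noise streams are split deterministically
    from ``seed`` using the community index as spawn key; the same seed
    yields a bit-identical TraceSet.
    """
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    traces = []
    for i in range(n_communities):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        param_seed, sim_seed = ss.spawn(2)
        circ_i = _community_params(circuit, np.random.default_rng(param_seed))
        traces.append(_simulate_core(program, circ_i, switch, sim_seed))
    degfp = np.column_stack([tr.degfp for tr in traces])
    mcherry = np.column_stack([tr.mcherry for tr in traces])
    ids = [f"community_{i:03d}" for i in range(n_communities)]
    meta = {
        "seed": int(seed),
        "program": program.to_dict(),
        "params_hash": _params_hash(program, circuit, switch),
        "mode": "ensemble",
    }
    return TraceSet(
        time_min=traces[0].time_min, degfp=degfp, mcherry=mcherry,
        community_ids=ids, meta=meta,
    )


def simulate_consortium(
    program: InputProgram,
    circuit_sensitive: CircuitParams,
    circuit_killer: CircuitParams,
    switch: SwitchParams,
    toxin: ToxinParams,
    n_sensitive: int,
    seed: int,
) -> Tuple[TraceSet, np.ndarray]:
    """Killer/sensitive consortium under a shared chemical rhythm.

    The killer promoter is simulated as one extra community (its own seed
    stream, no reporter); its ON state sources the shared toxin field
    ``dX/dt = toxin_rate * P_killer - toxin_decay_h * X``.  Sensitive
    communities use exactly the ensemble seed streams, so ``toxin_rate = 0``
    reproduces :func:`simulate_ensemble` element-wise.

    Returns the sensitive TraceSet and the toxin field sampled at the
    imaging cadence.
    """
    if n_sensitive < 1:
        raise ValueError("n_sensitive must be >= 1")
    n, per_sample, per_cycle = _steps(program, switch)
    dt = switch.dt_h
    # killer stream: length-2 spawn key can never collide with sensitive (i,) keys
    killer_ss = np.random.SeedSequence(entropy=seed, spawn_key=(0, 1))
    noise_seed, _ = killer_ss.spawn(2)
    _, c_sa, c_iaa = sample_program(program, dt_min=dt * 60.0)
    u_k = chemical_to_drive(c_sa, c_iaa, circuit_killer, dt)
    p_killer = simulate_switch(u_k, switch, noise_seed, period_h=program.period_h).state
    X = np.empty(n)
    x_val = 0.0
    for k in range(n):
        X[k] = x_val
        x_val += dt * (toxin.toxin_rate * p_killer[k] - toxin.toxin_decay_h * x_val)

    traces = []
    for i in range(n_sensitive):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        param_seed, sim_seed = ss.spawn(2)
        circ_i = _community_params(circuit_sensitive, np.random.default_rng(param_seed))
        traces.append(
            _simulate_core(program, circ_i, switch, sim_seed, toxin=toxin, toxin_field=X)
        )
    degfp = np.column_stack([tr.degfp for tr in traces])
    mcherry = np.column_stack([tr.mcherry for tr in traces])
    ids = [f"community_{i:03d}" for i in range(n_sensitive)]
    meta = {
        "seed": int(seed),
        "program": program.to_dict(),
        "params_hash": _params_hash(program, circuit_sensitive, switch),
        "mode": "consortium",
    }
    ts = TraceSet(
        time_min=traces[0].time_min, degfp=degfp, mcherry=mcherry,
        community_ids=ids, meta=meta,
    )
    return ts, X[::per_sample]
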