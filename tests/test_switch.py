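import numpy as np
import pytest

from chemsync import SwitchParams, hysteresis_width, simulate_switch, sync_index
from chemsync.switch import SwitchError, sweep_noise_rate, thresholds


def schmitt_oracle(u, mid, th_on, th_off):
    """Pen-and-paper Schmitt trigger: exhaustive crossing scan."""
    s = 1 if u[0] > mid else 0
    out = []
    for v in u:
        if s == 0 and v > th_on:
            s = 1
        elif s == 1 and v < th_off:
            s = 0
        out.append(s)
    return np.asarray(out, dtype=np.uint8)


class TestHysteresisWidth:
    def test_rate_term_vanishes_for_kappa_zero(self):
        p = SwitchParams(kappa=0.0)
        for T in (0.5, 2.0, 10.0, 100.0):
            assert hysteresis_width(T, p) == p.h0

    def test_width_law_arithmetic(self):
        p = SwitchParams(h0=0.2, kappa=1.25, T_ref_h=10.0)
        assert hysteresis_width(10.0, p) == pytest.approx(0.45)

    def test_width_decreases_with_period(self):
        p = SwitchParams(h0=0.1, kappa=1.25)
        assert hysteresis_width(2, p) > hysteresis_width(4, p) > hysteresis_width(10, p)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(SwitchError):
            hysteresis_width(0.0, SwitchParams())


class TestNoiselessSchmitt:
    def test_equivalence_with_exhaustive_scan_on_random_drives(self):
        """The trajectory equals the pen-and-paper evaluation on arbitrary inputs."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(5, 400)
            u = np.cumsum(rng.normal(0, 0.2, n))  # random walk drive
            mid = rng.uniform(-0.5, 0.5)
            h0 = rng.uniform(0.0, 0.8)
            p = SwitchParams(mid=mid, h0=h0, noise_sigma=0.0)
            tr = simulate_switch(u, p, seed=0)
            th_on, th_off = thresholds(p)
            assert np.array_equal(tr.state, schmitt_oracle(u, mid, th_on, th_off))

    def test_square_wave_gives_one_transition_pair_per_cycle(self):
        p = SwitchParams(noise_sigma=0.0)
        n_per = int(round(4.0 / p.dt_h))
        cycle = np.concatenate([np.full(n_per // 2, -1.0), np.full(n_per // 2, 1.0)])
        u = np.tile(cycle, 5)
        tr = simulate_switch(u, p, seed=0, period_h=4.0)
        flips = np.diff(tr.state.astype(int))
        # one ON per cycle; the OFF of the final cycle falls beyond the record
        assert np.count_nonzero(flips == 1) == 5
        assert np.count_nonzero(flips == -1) == 4
        on_times = tr.time_h[np.flatnonzero(flips == 1) + 1]
        assert np.allclose(np.diff(on_times), 4.0)

    def test_subthreshold_drive_never_flips(self):
        p = SwitchParams(mid=0.2, h0=0.4, noise_sigma=0.0)
        amp = 0.19  # below h/2
        u = p.mid + amp * np.sign(np.sin(np.linspace(0, 30, 2000)))
        tr = simulate_switch(u, p, seed=0)
        assert np.all(tr.state == tr.state[0])

    def test_exact_threshold_value_does_not_flip(self):
        p = SwitchParams(mid=0.0, h0=0.4, noise_sigma=0.0)
        u = np.array([-1.0, 0.2, 0.2, 1.0, 0.2, -0.2, -1.0])  # 0.2 == theta_on exactly
        tr = simulate_switch(u, p, seed=0)
        assert list(tr.state) == [0, 0, 0, 1, 1, 1, 0]

    def test_mirror_symmetry_of_transition_times(self):
        """Mapping u -> 2 mid - u and swapping labels preserves transitions."""
        rng = np.random.default_rng(7)
        u = np.cumsum(rng.normal(0, 0.3, 300))
        p = SwitchParams(mid=0.1, h0=0.3, noise_sigma=0.0)
        a = simulate_switch(u, p, seed=0).state.astype(int)
        b = simulate_switch(2 * p.mid - u, p, seed=0).state.astype(int)
        if u[0] != p.mid:  # avoid the tie in the initial-state indicator
            assert np.array_equal(a, 1 - b)


class TestNoisySwitch:
    def test_switching_rate_matches_step_size_refinement(self):
        """Mean alternation rate at dt agrees within 10% with a dt/10 reference."""
        def rate(dt_h, seed, dur=1000.0):
            p = SwitchParams(h0=0.4, noise_sigma=0.3, noise_tau_h=0.5, dt_h=dt_h)
            u = np.full(int(round(dur / dt_h)), p.mid)
            tr = simulate_switch(u, p, seed)
            return np.count_nonzero(np.diff(tr.state)) / dur

        coarse = np.mean([rate(1 / 960, s) for s in range(4)])
        fine = np.mean([rate(1 / 9600, 100 + s) for s in range(4)])
        assert abs(coarse - fine) / fine < 0.10

    def test_determinism_and_validation(self):
        p = SwitchParams()
        u = np.zeros(200)
        a = simulate_switch(u, p, seed=5)
        b = simulate_switch(u, p, seed=5)
        assert np.array_equal(a.state, b.state)
        with pytest.raises(SwitchError):
            simulate_switch(np.empty(0), p, seed=0)
        with pytest.raises(SwitchError):
            simulate_switch(np.array([np.nan]), p, seed=0)
        with pytest.raises(SwitchError):
            SwitchParams(noise_sigma=0.1, noise_tau_h=0.5, dt_h=0.2)  # dt too coarse


def _square_traj_set(p, period_h, amplitude, n_cycles, n_traj, supra=True):
    n_per = int(round(period_h / p.dt_h))
    cyc = np.concatenate([np.full(n_per // 2, -amplitude), np.full(n_per // 2, amplitude)])
    u = np.tile(cyc, n_cycles)
    return [simulate_switch(u, p, seed=i, period_h=period_h) for i in range(n_traj)]


class TestSyncIndex:
    def test_identical_noiseless_supra_threshold_locking_is_perfect(self):
        p = SwitchParams(noise_sigma=0.0)
        trajs = _square_traj_set(p, 4.0, 1.2, 5, 3)
        assert sync_index(trajs, 4.0, duration_h=20.0, mid=p.mid) == 1.0

    def test_frozen_state_scores_zero(self):
        p = SwitchParams(noise_sigma=0.0)
        n = int(round(20.0 / p.dt_h))
        u = np.full(n, 2.0)  # permanently above threshold: ON forever, no transitions
        trajs = [simulate_switch(u, p, seed=i) for i in range(3)]
        assert sync_index(trajs, 4.0, duration_h=20.0, mid=p.mid) == 0.0

    def test_mismatched_grids_rejected(self):
        p = SwitchParams(noise_sigma=0.0)
        t1 = simulate_switch(np.zeros(100), p, seed=0)
        t2 = simulate_switch(np.zeros(50), p, seed=0)
        with pytest.raises(SwitchError):
            sync_index([t1, t2], 4.0)


class TestSweep:
    def test_noiseless_column_is_perfect(self):
        p = SwitchParams()
        mat = sweep_noise_rate([0.0], [4.0], 1.2, p, n_rep=2, seed=1)
        assert np.all(mat == 1.0)

    def test_wider_hysteresis_extends_the_high_sync_noise_range(self):
        """With kappa > 0 the noise range sustaining sync > 0.9 at fast driving
        contains the corresponding range of the fixed-width switch."""
        noises = [0.0, 0.1, 0.3, 0.5]
        rate_dep = sweep_noise_rate(noises, [2.0], 1.2, SwitchParams(), 3, seed=11)
        fixed = sweep_noise_rate(noises, [2.0], 1.2, SwitchParams(kappa=0.0), 3, seed=11)
        good_rate_dep = {s for s, v in zip(noises, rate_dep[:, 0]) if v > 0.9}
        good_fixed = {s for s, v in zip(noises, fixed[:, 0]) if v > 0.9}
        assert good_fixed <= good_rate_dep
        assert 0.5 in good_rate_dep - good_fixed  # strictly wider at strong noise

    def test_tenfold_weaker_drive_degrades_sync_at_all_noisy_points(self):
        noises = [0.1, 0.3]
        strong = sweep_noise_rate(noises, [2.0, 4.0], 1.2, SwitchParams(), 3, seed=3)
        weak = sweep_noise_rate(noises, [2.0, 4.0], 0.12, SwitchParams(), 3, seed=3)
        assert np.all(weak < strong)
        assert np.all(weak < 0.5)

    def test_grid_validation(self):
        with pytest.raises(SwitchError):
            sweep_noise_rate([], [4.0], 1.0, SwitchParams(), 1, seed=0)
        with pytest.raises(SwitchError):
            sweep_noise_rate([0.1], [4.0], 1.0, SwitchParams(), 0, seed=0)
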