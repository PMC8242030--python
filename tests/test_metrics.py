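import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemsync import InputProgram
from chemsync.metrics import (
    MetricsError,
    compute_periods,
    cumulative_acf,
    doubling_ratios,
    find_peaks,
    phase_drift,
    power_spectrum,
    response_precision,
    sync_fraction,
)
from conftest import make_peakset


def brute_force_peaks(x, nups, ndowns):
    """Exhaustive scan restating the nups/ndowns definition."""
    d = np.diff(x)
    out = []
    for i in range(len(x)):
        if i - nups < 0 or i + ndowns > len(x) - 1:
            continue
        if not (d[i - 1] > 0 and d[i] < 0):
            continue
        if all(d[i - k] >= 0 for k in range(1, nups + 1)) and all(
            d[i + k - 1] <= 0 for k in range(1, ndowns + 1)
        ):
            out.append(i)
    return out


class TestFindPeaks:
    def test_triangle_with_exact_runs_is_a_peak(self):
        x = np.concatenate([np.arange(7.0), np.arange(5.0, -1.0, -1.0)])
        pk = find_peaks(x, nups=6, ndowns=6)
        assert len(pk) == 1
        assert pk.peak_times_min[0] == 6.0

    def test_five_rising_steps_are_not_enough(self):
        x = np.concatenate([np.arange(6.0), np.arange(4.0, -2.0, -1.0), [0.0]])
        pk = find_peaks(x, nups=6, ndowns=6)
        assert len(pk) == 0

    def test_equivalence_with_exhaustive_scan_on_random_traces(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(30, 500))
            # smoothed random walks produce realistic run structure
            x = np.convolve(rng.normal(size=n), np.ones(5) / 5, mode="same")
            idx_oracle = brute_force_peaks(x, 6, 6)
            pk = find_peaks(x, nups=6, ndowns=6, min_prominence=0.0)
            assert list(pk.peak_times_min.astype(int)) == idx_oracle

    def test_width_is_measured_at_half_prominence(self):
        # symmetric triangle: prominence = apex, half-prominence width = apex width/2
        x = np.concatenate([np.arange(11.0), np.arange(9.0, -1.0, -1.0)])
        t = np.arange(len(x), dtype=float) * 10.0
        pk = find_peaks(x, t, nups=6, ndowns=6)
        assert len(pk) == 1
        assert pk.prominences[0] == pytest.approx(10.0)
        assert pk.fwhp_min[0] == pytest.approx(100.0)  # 10 samples at dt=10

    def test_short_trace_rejected(self):
        with pytest.raises(MetricsError):
            find_peaks(np.zeros(10), nups=6, ndowns=6)


class TestPeriods:
    def test_examples(self):
        assert list(compute_periods(make_peakset([0, 240, 480]))) == [4.0, 4.0]
        assert list(compute_periods(make_peakset([0, 240, 720]))) == [4.0, 8.0]
        assert list(compute_periods(make_peakset([100]))) == []


class TestPrecision:
    @pytest.mark.parametrize(
        "wo, wi, expected", [(300, 300, 1.0), (450, 300, 0.8), (900, 300, 0.5)]
    )
    def test_examples(self, wo, wi, expected):
        assert response_precision(wo, wi) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        wo=st.floats(min_value=1.0, max_value=1e4),
        wi=st.floats(min_value=1.0, max_value=1e4),
        c=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_symmetric_and_scale_invariant(self, wo, wi, c):
        p = response_precision(wo, wi)
        assert 0 < p <= 1
        assert p == pytest.approx(response_precision(wi, wo))
        assert p == pytest.approx(response_precision(c * wo, c * wi), rel=1e-9)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(MetricsError):
            response_precision(0.0, 300.0)


def _jittered_trains(T_min, frac, n_comm, n_cyc, rng):
    return [
        make_peakset(np.arange(n_cyc) * T_min + rng.normal(0, frac * T_min, n_cyc))
        for _ in range(n_comm)
    ]


class TestPhaseDrift:
    def test_identical_trains_have_zero_drift(self):
        prog = InputProgram(4, 2, 500, 1, True, 40, 10)
        trains = [make_peakset(np.arange(10) * 240.0 + 30)] * 5
        assert phase_drift(trains, prog) == 0.0

    def test_recovers_engineered_two_percent_jitter(self):
        """Gaussian peak-time jitter of 2% of the period across 46 communities
        is read back as 2% +/- 0.5 drift."""
        prog = InputProgram(4, 2, 500, 1, True, 40, 10)
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals.append(phase_drift(_jittered_trains(240.0, 0.02, 46, 10, rng), prog))
        assert abs(np.mean(vals) - 2.0) < 0.5

    def test_invariant_to_a_common_time_offset(self):
        prog = InputProgram(4, 2, 500, 1, True, 40, 10)
        rng = np.random.default_rng(5)
        base = [np.arange(10) * 240.0 + rng.normal(0, 5, 10) for _ in range(8)]
        a = phase_drift([make_peakset(t) for t in base], prog)
        b = phase_drift([make_peakset(t + 17.0) for t in base], prog)
        assert a == pytest.approx(b, rel=1e-9)

    def test_errors(self):
        prog = InputProgram(4, 2, 500, 1, True, 40, 10)
        with pytest.raises(MetricsError):
            phase_drift([make_peakset([100.0])], prog)
        with pytest.raises(MetricsError):
            phase_drift([make_peakset([]), make_peakset([])], prog)


class TestSyncFraction:
    def _prog(self, n_cyc=12):
        return InputProgram(4, 2, 500, 1, True, 4 * n_cyc, 10)

    def test_fully_locked_ensemble_scores_one(self):
        prog = self._prog()
        trains = [make_peakset(np.arange(12) * 240.0 + 30 + j) for j in range(5)]
        assert sync_fraction(trains, prog) == 1.0

    def test_half_peakless_scores_half(self):
        prog = self._prog()
        locked = [make_peakset(np.arange(12) * 240.0 + 30) for _ in range(3)]
        silent = [make_peakset([]) for _ in range(3)]
        assert sync_fraction(locked + silent, prog) == 0.5

    def test_recovers_a_constructed_98_percent_locked_ensemble(self):
        prog = self._prog()
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            trains = []
            for c in range(100):
                if c < 98:
                    t = np.arange(12) * 240.0 + rng.uniform(-30, 30, 12)
                else:
                    t = rng.uniform(0, 12 * 240.0, 12)
                trains.append(make_peakset(t))
            vals.append(sync_fraction(trains, prog))
        assert abs(np.mean(vals) - 0.98) <= 0.02


class TestSpectra:
    def test_cosine_acf_peaks_at_its_period(self):
        dt, T_h = 10.0, 4.0
        t = np.arange(0, 48 * 60, dt)
        x = np.cos(2 * np.pi * t / (T_h * 60))
        lag, acf = cumulative_acf(x[:, None], t)
        k = int(round(T_h / (dt / 60)))
        assert acf[k] > acf[k - 6] and acf[k] > acf[k + 6]
        assert acf[k] > 0.9

    def test_white_noise_acf_stays_inside_the_bartlett_band(self):
        rng = np.random.default_rng(0)
        n = 1000
        x = rng.normal(size=n)
        _, acf = cumulative_acf(x[:, None], np.arange(n) * 10.0)
        frac_inside = np.mean(np.abs(acf[1:]) < 3 / np.sqrt(n))
        assert frac_inside >= 0.99

    def test_period_doubled_train_moves_the_acf_maximum_to_2T(self):
        dt = 10.0
        t = np.arange(0, 96 * 60, dt)
        # bursts every 2T for T = 4 h
        x = np.exp(-((t % (8 * 60)) - 60) ** 2 / (2 * 30**2))
        lag, acf = cumulative_acf((x - x.mean())[:, None], t)
        k1 = int(round(4.0 * 6))
        k2 = int(round(8.0 * 6))
        assert acf[k2] > acf[k1]
        assert acf[k2] > 0.5

    def test_single_tone_dominant_period(self):
        dt = 10.0
        t = np.arange(0, 48 * 60, dt)
        x = np.sin(2 * np.pi * t / 240.0)
        _, _, dom = power_spectrum(x[:, None], t)
        bin_width = 1.0 / (4 * 48.0)
        assert abs(1 / dom - 1 / 4.0) <= bin_width

    def test_stronger_low_frequency_tone_wins(self):
        dt = 10.0
        t = np.arange(0, 96 * 60, dt)
        x = 0.5 * np.sin(2 * np.pi * t / 240.0) + 1.5 * np.sin(2 * np.pi * t / 480.0)
        _, _, dom = power_spectrum(x[:, None], t)
        assert dom == pytest.approx(8.0, rel=0.05)

    def test_parseval_identity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=512)
        t = np.arange(512) * 10.0
        _, power, _ = power_spectrum(x[:, None], t)
        xm = x - x.mean()
        assert np.sum(power) == pytest.approx(np.mean(xm**2), rel=1e-6)

    def test_acf_and_psd_agree_on_the_dominant_period(self):
        dt = 10.0
        t = np.arange(0, 72 * 60, dt)
        x = np.sin(2 * np.pi * t / 360.0) + 0.1 * np.cos(2 * np.pi * t / 90.0)
        lag, acf = cumulative_acf((x - x.mean())[:, None], t)
        # dominant positive-lag ACF maximum
        k = np.argmax(acf[6:]) + 6
        _, _, dom = power_spectrum(x[:, None], t)
        assert lag[k] == pytest.approx(dom, abs=dt / 60)

    def test_degenerate_inputs_rejected(self):
        t = np.arange(100) * 10.0
        with pytest.raises(MetricsError):
            power_spectrum(np.ones((100, 1)), t)
        with pytest.raises(MetricsError):
            cumulative_acf(np.random.default_rng(0).normal(size=(100, 1)), t, max_lag_h=20.0)


class TestDoublingRatios:
    def _prog(self):
        return InputProgram(4, 2, 500, 1, True, 48, 10)

    def test_matched_periods_snap_to_one(self):
        trains = [make_peakset(np.arange(10) * 240.0) for _ in range(4)]
        raw, snapped = doubling_ratios(trains, self._prog())
        assert np.all(raw == 1.0) and np.all(snapped == 1.0)

    def test_snapping_rule(self):
        trains = [
            make_peakset(np.arange(6) * 1.9 * 240.0),  # ratio 1.9 -> snaps to 2
            make_peakset(np.arange(6) * 1.4 * 240.0),  # ratio 1.4 -> unsnapped
        ]
        raw, snapped = doubling_ratios(trains, self._prog())
        assert raw[0] == pytest.approx(1.9) and snapped[0] == 2.0
        assert raw[1] == pytest.approx(1.4) and np.isnan(snapped[1])

    def test_communities_without_two_peaks_are_omitted(self):
        trains = [make_peakset([100.0]), make_peakset(np.arange(5) * 240.0)]
        raw, _ = doubling_ratios(trains, self._prog())
        assert len(raw) == 1
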