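"""Synthetic PPG generation, noise calibration, and pulse-parameter fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from spikehr import signals as sg


class TestGeneratePPG:
    def test_constant_60bpm_has_one_second_beats(self, ppg60):
        peaks, _ = sps.find_peaks(ppg60.samples, prominence=0.05)
        assert np.allclose(np.diff(peaks) / ppg60.fs, 1.0, atol=1 / ppg60.fs)

    def test_peak_value_matches_dense_evaluation(self, ppg60, table_pulse):
        # brute-force the pulse profile over one period on a dense phase grid
        theta = np.linspace(-np.pi, np.pi, 400001)
        dense_max = table_pulse.profile(theta).max()
        assert abs(ppg60.samples.max() - dense_max) < 1e-3  # 1/fs phase resolution

    def test_zero_amplitudes_give_zero_waveform(self):
        pulse = sg.PPGPulseSpec(a1=0.0, a2=0.0)
        w = sg.generate_ppg(sg.HRTrajectory.constant(80), pulse, fs=125, duration=5)
        assert np.all(w.samples == 0)

    @pytest.mark.parametrize("hr", [65, 90, 115, 140])
    def test_phase_conservation_beat_count(self, hr):
        T = 20.0
        w = sg.generate_ppg(sg.HRTrajectory.constant(hr), fs=125, duration=T)
        peaks, _ = sps.find_peaks(w.samples, prominence=0.05)
        assert abs(len(peaks) - int(T * hr / 60)) <= 1

    def test_time_varying_hr_is_phase_continuous(self):
        traj = sg.HRTrajectory.staircase([60, 120], 5.0)
        w = sg.generate_ppg(traj, fs=125, duration=10)
        # no sample-to-sample jump larger than the steepest pulse slope
        assert np.max(np.abs(np.diff(w.samples))) < 0.05

    def test_invalid_arguments(self):
        traj = sg.HRTrajectory.constant(60)
        with pytest.raises(ValueError):
            sg.generate_ppg(traj, fs=125, duration=0)
        with pytest.raises(ValueError):
            sg.generate_ppg(traj, fs=20, duration=5)
        with pytest.raises(ValueError):
            sg.HRTrajectory.constant(170)  # outside declared range


class TestSignalPower:
    def test_zero_constant_and_sinusoid(self):
        assert sg.signal_power(sg.Waveform(np.zeros(100), 100)) == 0
        assert sg.signal_power(sg.Waveform(np.full(100, 3.0), 100)) == pytest.approx(9.0)
        t = np.arange(1000) / 100.0  # integer number of periods
        w = sg.Waveform(np.sin(2 * np.pi * 2 * t), 100)
        assert sg.signal_power(w) == pytest.approx(0.5, abs=1e-12)

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError):
            sg.signal_power(sg.Waveform(np.empty(0), 100))


class TestNoise:
    @pytest.mark.parametrize("snr,ratio", [(0.0, 1.0), (10.0, 0.1)])
    def test_noise_power_calibration(self, ppg60, snr, ratio):
        noisy = sg.add_noise(ppg60, sg.NoiseSpec(snr, "white", seed=7))
        p_n = np.mean((noisy.samples - ppg60.samples) ** 2)
        assert p_n / sg.signal_power(ppg60) == pytest.approx(ratio, rel=1e-9)

    @pytest.mark.parametrize("color", sorted(sg.NOISE_COLORS))
    def test_unit_power_all_colors_large_n(self, color):
        n = sg.colored_noise(2**20, color, seed=3)
        assert np.mean(n**2) == pytest.approx(1.0, rel=0.02)
        assert abs(np.mean(n)) < 0.01

    def test_pink_spectrum_slope(self):
        n = sg.colored_noise(2**20, "pink", seed=1)
        f, P = sps.periodogram(n)
        m = (f > 1e-3) & (f < 1e-2)  # one decade
        slope = np.polyfit(np.log(f[m]), np.log(P[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    @pytest.mark.parametrize("color,sign", [("brown", -1), ("blue", +1), ("violet", +1)])
    def test_colored_slope_sign(self, color, sign):
        n = sg.colored_noise(2**18, color, seed=2)
        f, P = sps.periodogram(n)
        m = (f > 1e-3) & (f < 1e-1)
        slope = np.polyfit(np.log(f[m]), np.log(P[m]), 1)[0]
        assert np.sign(slope) == sign

    def test_seed_determinism(self, ppg60):
        a = sg.add_noise(ppg60, sg.NoiseSpec(5, "pink", seed=42))
        b = sg.add_noise(ppg60, sg.NoiseSpec(5, "pink", seed=42))
        assert np.array_equal(a.samples, b.samples)

    def test_zero_power_signal_rejected(self):
        w = sg.Waveform(np.zeros(1000), 125)
        with pytest.raises(ValueError):
            sg.add_noise(w, sg.NoiseSpec(10))

    def test_unknown_color_rejected(self):
        with pytest.raises(ValueError):
            sg.NoiseSpec(10, "plaid")


def _gauge_invariants(spec, omega):
    """Identifiable pulse content: amplitudes, widths, center separation,
    and the joint phase of each center with the offset time."""
    wrap = lambda x: np.arctan2(np.sin(x), np.cos(x))
    return dict(
        a1=spec.a1, a2=spec.a2, b1=spec.b1, b2=spec.b2,
        dtheta=wrap(spec.theta1 - spec.theta2),
        phase1=wrap(spec.theta1 + omega * spec.t0),
    )


class TestPulseFit:
    def test_recovery_from_clean_pulse(self, table_pulse):
        traj = sg.HRTrajectory.constant(60)
        w = sg.generate_ppg(traj, table_pulse, fs=500, duration=4)
        fit = sg.fit_pulse_params(w, traj)
        omega = 2 * np.pi
        truth = _gauge_invariants(table_pulse, omega)
        got = _gauge_invariants(fit, omega)
        for k, v in truth.items():
            assert got[k] == pytest.approx(v, rel=0.05, abs=0.05), k
        # the fitted spec reproduces the waveform it was fitted to
        w2 = sg.generate_ppg(traj, fit, fs=500, duration=4)
        assert np.max(np.abs(w.samples - w2.samples)) < 0.02 * table_pulse.a1

    def test_flat_waveform_fails(self):
        traj = sg.HRTrajectory.constant(60)
        with pytest.raises(sg.PulseFitError):
            sg.fit_pulse_params(sg.Waveform(np.zeros(500), 125), traj)

    def test_mean_a1_under_noise_within_printed_dispersion(self, table_pulse):
        traj = sg.HRTrajectory.constant(60)
        w = sg.generate_ppg(traj, table_pulse, fs=250, duration=4)
        a1s = []
        for seed in range(10):
            noisy = sg.add_noise(w, sg.NoiseSpec(20, "white", seed=seed))
            a1s.append(sg.fit_pulse_params(noisy, traj).a1)
        assert 0.17 <= np.mean(a1s) <= 0.21  # printed 0.19 +- 0.02


@settings(deadline=None, max_examples=20, derandomize=True)
@given(hr=st.floats(60, 150), seed=st.integers(0, 2**16))
def test_noise_is_zero_mean_and_exactly_calibrated(hr, seed):
    w = sg.generate_ppg(sg.HRTrajectory.constant(hr), fs=125, duration=4)
    noisy = sg.add_noise(w, sg.NoiseSpec(6.0, "white", seed=seed))
    p_n = np.mean((noisy.samples - w.samples) ** 2)
    assert p_n == pytest.approx(sg.signal_power(w) * 10 ** -0.6, rel=1e-9)
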