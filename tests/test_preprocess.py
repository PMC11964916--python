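"""Filter bank, rectification, and LIF spike encoding."""

import numpy as np
import pytest
from scipy import signal as sps

from spikehr import preprocess as pp
from spikehr import signals as sg


class TestBands:
    def test_wide_band_edges_in_hz(self):
        e1 = pp.WIDE_BANDS[0]
        assert e1.low_hz == pytest.approx(1.0)
        assert e1.high_hz == pytest.approx(82 / 60)

    def test_narrow_band_set(self):
        edges = [(b.low_bpm, b.high_bpm) for b in pp.NARROW_BANDS]
        assert edges == [(60, 80), (80, 88), (88, 96), (96, 150)]

    def test_boundary_bands_flank_the_range(self):
        cfg = pp.FilterBankConfig(include_boundary=True)
        bands = cfg.all_bands
        assert len(bands) == 6
        assert bands[0].high_bpm == 60 and bands[-1].low_bpm == 150

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            pp.BandSpec(90, 80)


class TestFilterBank:
    def test_sinusoid_lands_in_its_band(self):
        cfg = pp.FilterBankConfig()
        f = pp.WIDE_BANDS[1].center_bpm / 60.0  # center of e2
        t = np.arange(125 * 30) / 125.0
        w = sg.Waveform(np.sin(2 * np.pi * f * t), 125)
        powers = [np.mean(ch.samples[1250:] ** 2) for ch in pp.apply_filter_bank(w, cfg)]
        assert int(np.argmax(powers)) == 1

    def test_zero_input_zero_output(self):
        w = sg.Waveform(np.zeros(1000), 125)
        for ch in pp.apply_filter_bank(w, pp.FilterBankConfig()):
            assert np.all(ch.samples == 0)

    def test_band_above_nyquist_rejected(self):
        w = sg.Waveform(np.zeros(1000), 125)
        cfg = pp.FilterBankConfig(bands=(pp.BandSpec(60, 8000),))
        with pytest.raises(ValueError):
            pp.apply_filter_bank(w, cfg)


class TestRectifyAmplify:
    def test_absolute_value(self):
        w = sg.Waveform(np.array([-1.0, 2.0, -3.0]), 10)
        assert np.array_equal(pp.rectify_amplify(w, 1.0).samples, [1, 2, 3])

    def test_studied_gain_scales(self):
        w = sg.Waveform(np.array([-1.0, 2.0, -3.0]), 10)
        assert np.array_equal(pp.rectify_amplify(w, 8.0).samples,
                              8 * pp.rectify_amplify(w, 1.0).samples)

    def test_rectified_sinusoid_doubles_frequency(self):
        t = np.arange(125 * 20) / 125.0
        w = sg.Waveform(np.sin(2 * np.pi * 2.0 * t), 125)
        r = pp.rectify_amplify(w, 1.0)
        f, P = sps.periodogram(r.samples - r.samples.mean(), fs=125)
        assert f[np.argmax(P)] == pytest.approx(4.0, abs=0.1)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            pp.rectify_amplify(sg.Waveform(np.ones(4), 10), 0.0)


class TestLIFEncode:
    def test_zero_current_no_spikes(self):
        st = pp.lif_encode(sg.Waveform(np.zeros(1000), 1000), pp.LIFParams())
        assert len(st) == 0

    def test_constant_current_isi_matches_closed_form(self):
        # dv/dt = -v/tau + I: ISI = tau * ln(I*tau / (I*tau - v_thr))
        p = pp.LIFParams(tau=0.024, v_thr=1.0)
        fs = 10000.0
        I = 100.0  # I*tau = 2.4 > 1
        st = pp.lif_encode(sg.Waveform(np.full(int(fs * 2), I), fs), p)
        isi = np.diff(st.times)
        expected = p.tau * np.log(I * p.tau / (I * p.tau - p.v_thr))
        assert np.all(np.abs(isi - expected) <= 1.5 / fs)

    def test_rate_monotone_in_current(self):
        p = pp.LIFParams(tau=0.024, v_thr=1.0)
        fs = 2000.0
        counts = [len(pp.lif_encode(sg.Waveform(np.full(int(fs), I), fs), p))
                  for I in (50, 80, 120, 200, 400)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_higher_threshold_fewer_spikes(self, ppg60):
        cfg = pp.FilterBankConfig()
        n = [sum(len(t) for t in pp.preprocess_pipeline(
                ppg60, cfg, pp.LIFParams(v_thr=v, unit_dc_gain=True)))
             for v in (0.5, 1.0, 2.0)]
        assert n[0] > n[1] > n[2] > 0

    def test_refractory_caps_rate(self):
        p = pp.LIFParams(tau=0.02, v_thr=1.0, refractory=0.01)
        fs = 5000.0
        st = pp.lif_encode(sg.Waveform(np.full(int(fs), 1000.0), fs), p)
        assert np.min(np.diff(st.times)) >= 0.01

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            pp.LIFParams(tau=-1)
        with pytest.raises(ValueError):
            pp.LIFParams(v_thr=0.0, v_reset=0.0)


class TestPipeline:
    @pytest.mark.parametrize("hr,band", [(65, 0), (90, 1), (95, 1), (115, 2), (140, 3)])
    def test_band_selectivity(self, hr, band):
        w = sg.generate_ppg(sg.HRTrajectory.constant(hr), fs=125, duration=30)
        trains = pp.preprocess_pipeline(w)
        rates = [t.rate() for t in trains]
        assert int(np.argmax(rates)) == band

    def test_silence_in_silence_out(self):
        w = sg.Waveform(np.zeros(125 * 10), 125)
        assert all(len(t) == 0 for t in pp.preprocess_pipeline(w))

    def test_spike_times_strictly_increasing(self, ppg60):
        for t in pp.preprocess_pipeline(ppg60):
            if len(t) > 1:
                assert np.all(np.diff(t.times) > 0)
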