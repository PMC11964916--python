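"""Decoder and state-machine builders and readouts."""

import numpy as np
import pytest
from dataclasses import replace

from spikehr import architectures as ar
from spikehr import network as nw
from spikehr import preprocess as pp
from spikehr import signals as sg


class TestDecoderBuild:
    def test_layer_size_and_weight_shape(self):
        cfg = ar.DecoderConfig()
        spec = ar.build_decoder(cfg)
        assert spec.n_neurons == 13
        W = ar.decoder_weight_matrix(cfg)
        assert W.shape == (13, 6)

    def test_weights_are_gaussian_in_bpm_distance(self):
        cfg = ar.DecoderConfig()
        W = ar.decoder_weight_matrix(cfg)
        centers = cfg.centers
        betas = np.array([b.center_bpm for b in cfg.filter_bank.all_bands])
        sig = cfg.sigma_spacing * cfg.spacing
        raw = np.exp(-((centers[:, None] - betas[None, :]) ** 2) / (2 * sig**2))
        # proportional per row after normalization
        for k in range(13):
            ratio = W[k] / raw[k]
            assert np.allclose(ratio, ratio[0])

    def test_rows_sum_to_constant(self):
        W = ar.decoder_weight_matrix(ar.DecoderConfig())
        assert np.allclose(W.sum(axis=1), W.sum(axis=1)[0])

    def test_sigma_zero_is_nearest_band_delta(self):
        cfg = replace(ar.DecoderConfig(), sigma_spacing=0.0)
        W = ar.decoder_weight_matrix(cfg)
        assert np.all((W > 0).sum(axis=1) == 1)


class TestDecodeHR:
    def test_delta_profile_returns_center(self):
        cfg = ar.DecoderConfig()
        rates = np.zeros(13)
        rates[4] = 30.0
        assert ar.decode_hr(rates, cfg) == pytest.approx(cfg.centers[4])

    def test_zero_profile_is_nan(self):
        assert np.isnan(ar.decode_hr(np.zeros(13)))

    @pytest.mark.parametrize("center", [75.0, 97.5, 120.0, 123.75])
    def test_gaussian_bump_peak_matches_grid_oracle(self, center):
        cfg = ar.DecoderConfig()
        rates = 40 * np.exp(-((cfg.centers - center) ** 2) / (2 * 10.0**2))
        decoded = ar.decode_hr(rates, cfg)
        # independent oracle: dense quadratic-free argmax of the smoothed
        # profile via parabola through the three points around the max
        prof = ar._smooth_profile(rates, cfg)
        m = int(np.argmax(prof))
        den = prof[m - 1] - 2 * prof[m] + prof[m + 1]
        oracle = cfg.centers[m] + 0.5 * (prof[m - 1] - prof[m + 1]) / den * cfg.spacing
        assert decoded == pytest.approx(oracle, abs=1e-9)
        assert decoded == pytest.approx(center, abs=1.0)

    def test_full_chain_constant_hr(self):
        cfg = ar.DecoderConfig()
        w = sg.generate_ppg(sg.HRTrajectory.constant(95), fs=125, duration=30)
        trains = pp.preprocess_pipeline(w, cfg.filter_bank)
        raster = ar.run_decoder(trains, cfg, duration=30)
        t, est = ar.decode_hr_series(raster, cfg)
        assert np.nanmean(est[t > 5]) == pytest.approx(95, abs=3.0)


class TestBuilders:
    def test_wta_neuron_count(self):
        assert ar.build_wta().n_neurons == 4 * 16 + 16  # 80

    @pytest.mark.parametrize("build", [ar.build_nnnsm, ar.build_mononsm])
    def test_gated_neuron_count(self, build):
        assert build().n_neurons == 80 + 4 * (16 + 4)  # 160

    def test_wrong_block_rejected(self):
        with pytest.raises(ValueError):
            ar.build_wta(ar.NNNSM_PARAMS)
        with pytest.raises(ValueError):
            ar.build_nnnsm(ar.MONONSM_PARAMS)

    def test_nn_adjacency_is_tridiagonal(self):
        A = ar.disinh_adjacency(ar.NNNSM_PARAMS)
        expected = np.abs(np.subtract.outer(range(4), range(4))) <= 1
        assert np.array_equal(A, expected)

    def test_mono_adjacency_is_upward_only(self):
        A = ar.disinh_adjacency(ar.MONONSM_PARAMS)
        d = np.subtract.outer(range(4), range(4))
        assert np.array_equal(A, (d == 0) | (d == -1))

    def test_table_probabilities_are_verbatim(self):
        assert ar.WTA_PARAMS.p_inh_exc[1] == 0.45
        assert ar.NNNSM_PARAMS.p_exc_exc[3] == 0.80
        assert ar.MONONSM_PARAMS.p_inh_inh == 0.50
        assert ar.NNNSM_PARAMS.p_ex_disinh0 == 1.0
        assert ar.MONONSM_PARAMS.p_ex_disinh0 == 0.5


class TestStateReadout:
    def _raster(self, active="e3", rate=30.0, duration=4.0):
        spec = ar.build_wta()
        slices = spec.offsets()
        lo, hi = slices[active]
        n = hi - lo
        times = np.sort(np.tile(np.linspace(0.01, duration - 0.01,
                                            int(rate * duration)), n))
        ids = np.tile(np.arange(lo, hi), int(rate * duration))
        return nw.SpikeRaster(times, ids, slices, duration)

    def test_single_active_population_decodes_constantly(self):
        trace = ar.read_state(self._raster("e3"))
        assert all(lab == "e3" for lab in trace.labels)

    def test_zero_margin_is_pure_argmax(self):
        trace = ar.read_state(self._raster("e2"), margin=0.0)
        assert all(lab == "e2" for lab in trace.labels)

    def test_silent_raster_is_none(self):
        r = nw.SpikeRaster(np.empty(0), np.empty(0, int),
                           ar.build_wta().offsets(), 2.0)
        trace = ar.read_state(r)
        assert all(lab == "none" for lab in trace.labels)


class TestDynamics:
    def test_wta_winner_follows_dominant_input(self):
        spec = ar.build_wta(seed=0)
        r = ar.drive_state_machine(spec, [10.0, 60.0, 10.0, 10.0],
                                   duration=4.0, seed=1)
        rates = r.mean_rates()
        assert max(("e1", "e2", "e3", "e4"), key=rates.get) == "e2"

    def test_wta_agrees_with_rate_oracle(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            dom = int(rng.integers(0, 4))
            base = rng.uniform(40, 80)
            rates = base * rng.uniform(0.0, 0.7, 4)
            rates[dom] = base
            winner_oracle, _ = nw.wta_rate_oracle(rates)
            spec = ar.build_wta(mismatch_cv=0.2, seed=300 + s)
            r = ar.drive_state_machine(spec, list(rates), duration=4.0, seed=400 + s)
            counts = [len(r.population_events(f"e{i+1}")[0]) for i in range(4)]
            hits += int(np.argmax(counts)) == winner_oracle
        assert hits >= 9

    def test_transition_time_zero_rate_never_fires(self):
        spec = ar.build_wta(seed=0)
        assert ar.measure_transition_time(spec, 0, 2, 0.0, trial_time=4.0) == np.inf

    def test_transition_time_paired_rates(self):
        spec = ar.build_wta(seed=1)
        t_lo = ar.measure_transition_time(spec, 0, 2, 60.0, seed=1, trial_time=8.0)
        t_hi = ar.measure_transition_time(spec, 0, 2, 160.0, seed=1, trial_time=8.0)
        assert t_hi <= t_lo

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            ar.measure_transition_time(ar.build_wta(), 0, 7, 50.0)


class TestParamsConfig:
    @pytest.mark.parametrize("params", [ar.WTA_PARAMS, ar.NNNSM_PARAMS,
                                        ar.MONONSM_PARAMS])
    def test_key_value_roundtrip(self, params):
        cfg = ar.params_to_config(params)
        assert cfg["p_exc_exc_ex0"] == 0.85 and cfg["p_inp_ex2"] == 0.30
        assert ar.params_from_config(cfg) == params

    def test_unknown_key_rejected(self):
        cfg = ar.params_to_config(ar.WTA_PARAMS)
        cfg["p_ghost"] = 1.0
        with pytest.raises(ValueError, match="p_ghost"):
            ar.params_from_config(cfg)
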