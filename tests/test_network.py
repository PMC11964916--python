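"""Clock-driven LIF network simulator: connectivity, dynamics, rate readout,
and the winner-take-all rate-equation oracle."""

import numpy as np
import pytest

from spikehr import network as nw
from spikehr.preprocess import LIFParams

LIF = LIFParams(tau=0.02, v_thr=1.0, v_reset=0.0, refractory=0.0)


def two_pops(p, n_a=4, n_b=4):
    return nw.NetworkSpec(
        [nw.PopulationSpec("a", n_a, "excitatory", LIF),
         nw.PopulationSpec("b", n_b, "excitatory", LIF)],
        [nw.ConnectionSpec("a", "b", p, 0.5)], seed=0)


class TestRealize:
    def test_full_wiring(self):
        net = nw.realize_connectivity(two_pops(1.0))
        assert net.edge_count(0) == 16

    def test_no_wiring(self):
        net = nw.realize_connectivity(two_pops(0.0))
        assert net.edge_count(0) == 0

    def test_recurrent_excludes_autapses(self):
        spec = nw.NetworkSpec([nw.PopulationSpec("a", 5, "excitatory", LIF)],
                              [nw.ConnectionSpec("a", "a", 1.0, 0.5)])
        net = nw.realize_connectivity(spec)
        assert net.edge_count(0) == 20  # 5*5 - diagonal
        assert all(pre != post for pre, post in net.edges[0])

    def test_binomial_edge_count(self):
        counts = [nw.realize_connectivity(two_pops(0.85, 16, 16), seed=s).edge_count(0)
                  for s in range(100)]
        se = np.sqrt(256 * 0.85 * 0.15) / 10
        assert np.mean(counts) == pytest.approx(217.6, abs=4 * se)

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError):
            nw.NetworkSpec([nw.PopulationSpec("a", 2)],
                           [nw.ConnectionSpec("a", "ghost", 0.5, 1.0)])

    def test_sign_role_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nw.NetworkSpec([nw.PopulationSpec("a", 2, "inhibitory")],
                           [nw.ConnectionSpec("a", "a", 0.5, +1.0)])


class TestSimulate:
    def test_quiescent_without_input(self):
        spec = two_pops(0.5)
        raster = nw.simulate(spec, {}, duration=0.5, dt=1e-3)
        assert len(raster) == 0

    def test_driven_neuron_matches_closed_form_rate(self):
        spec = nw.NetworkSpec([nw.PopulationSpec("n", 1, "excitatory", LIF)], [])
        R, w, tau_s = 50.0, 1.0, 0.1
        train = nw.SpikeTrainInput(np.arange(0.0, 10.0, 1 / R), weight=w,
                                   probability=1.0, synapse_tau=tau_s)
        raster = nw.simulate(spec, {"n": train}, duration=10.0, dt=1e-4)
        t, _ = raster.population_events("n")
        measured = np.sum(t > 1.0) / 9.0
        D = w * R * tau_s  # steady drive in threshold units
        expected = 1.0 / (LIF.tau * np.log(D / (D - 1.0)))
        assert measured == pytest.approx(expected, rel=0.05)

    def test_events_within_duration_and_sorted(self):
        spec = two_pops(0.5)
        inp = {"a": nw.PoissonInput(rate=200, weight=1.0, probability=1.0, n_sources=8)}
        r = nw.simulate(spec, inp, duration=1.0, dt=1e-3, seed=5)
        assert len(r) > 0
        assert np.all((r.times >= 0) & (r.times <= 1.0))
        assert np.all(np.diff(r.times) >= 0)

    def test_seed_determinism(self):
        spec = two_pops(0.6)
        inp = {"a": nw.PoissonInput(rate=100, weight=1.0, probability=0.5)}
        r1 = nw.simulate(spec, inp, duration=1.0, dt=1e-3, seed=9)
        r2 = nw.simulate(spec, inp, duration=1.0, dt=1e-3, seed=9)
        r3 = nw.simulate(spec, inp, duration=1.0, dt=1e-3, seed=10)
        assert np.array_equal(r1.times, r2.times) and np.array_equal(r1.ids, r2.ids)
        assert not (len(r3) == len(r1) and np.array_equal(r3.times, r1.times))

    def test_runaway_excitation_signalled(self):
        spec = nw.NetworkSpec([nw.PopulationSpec("a", 16, "excitatory", LIF)],
                              [nw.ConnectionSpec("a", "a", 1.0, 50.0, 0.1)])
        inp = {"a": nw.PoissonInput(rate=500, weight=5.0, probability=1.0)}
        with pytest.raises(nw.RunawayExcitationError):
            nw.simulate(spec, inp, duration=2.0, dt=1e-3, rate_cap=200)

    def test_ei_balance_mean_currents_cancel(self):
        lif_i = LIFParams(tau=0.02, v_thr=1.0, refractory=0.003)
        lif_e = LIFParams(tau=0.02, v_thr=1.0, refractory=0.005)
        spec = nw.NetworkSpec(
            [nw.PopulationSpec("e", 64, "excitatory", lif_e),
             nw.PopulationSpec("i", 16, "inhibitory", lif_i)],
            [nw.ConnectionSpec("e", "e", 0.1, 0.05, 0.1),
             nw.ConnectionSpec("e", "i", 0.5, 0.6, 0.01),
             nw.ConnectionSpec("i", "e", 0.5, -0.8, 0.01),
             nw.ConnectionSpec("i", "i", 0.2, -0.1, 0.01)], seed=1)
        inp = {"e": nw.PoissonInput(rate=80, weight=0.6, probability=0.4, n_sources=32)}
        r = nw.simulate(spec, inp, duration=5.0, dt=5e-4, seed=2)
        lo, hi = r.pop_slices["e"]
        pos = r.mean_drive_exc[lo:hi].mean()
        neg = -r.mean_drive_inh[lo:hi].mean()
        assert neg / pos == pytest.approx(1.0, abs=0.3)

    def test_dt_above_one_ms_rejected(self):
        with pytest.raises(ValueError):
            nw.simulate(two_pops(0.5), {}, duration=1.0, dt=2e-3)


class TestPopulationRate:
    def _raster(self, times, ids, n=16, duration=1.0):
        return nw.SpikeRaster(np.asarray(times, float), np.asarray(ids),
                              {"p": (0, n)}, duration)

    def test_counts_per_neuron(self):
        times = np.sort(np.tile(np.linspace(0.01, 0.99, 25), 16))
        ids = np.tile(np.arange(16), 25)
        t, r = nw.population_rate(self._raster(times, ids), "p", window=1.0)
        assert r == pytest.approx([25.0])

    def test_empty_raster_zero_series(self):
        t, r = nw.population_rate(self._raster([], []), "p", window=0.25, step=0.25)
        assert np.all(r == 0) and len(r) == 4

    def test_poisson_rate_recovered(self, rng):
        lam, n, T = 40.0, 16, 5.0
        times = np.sort(rng.uniform(0, T, rng.poisson(lam * n * T)))
        ids = rng.integers(0, n, len(times))
        _, r = nw.population_rate(self._raster(times, ids, n, T), "p", window=T)
        se = np.sqrt(lam * n * T) / (n * T)
        assert abs(r[0] - lam) < 3 * se

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            nw.population_rate(self._raster([], []), "p", window=0.1, step=0.5)


class TestWTAOracle:
    def test_largest_input_wins(self):
        winner, rates = nw.wta_rate_oracle([1.0, 3.0, 2.0, 0.0], gamma=50.0)
        assert winner == 1
        assert rates[1] == pytest.approx(3.0, rel=1e-3)
        losers = np.delete(rates, 1)
        assert np.all(losers < 1e-3 * rates[1])

    def test_tie_signalled(self):
        with pytest.raises(nw.WTATieError):
            nw.wta_rate_oracle([2.0, 2.0, 1.0])

    def test_agrees_with_argmax_on_random_inputs(self, rng):
        for _ in range(100):
            I = rng.uniform(0.0, 5.0, 4)
            winner, _ = nw.wta_rate_oracle(I)
            assert winner == int(np.argmax(I))

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            nw.wta_rate_oracle([1.0, 2.0], gamma=0.0)
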