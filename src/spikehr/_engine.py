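"""Numba kernels for LIF integration and the clock-driven network simulator.

Membrane update uses the exact exponential step for piecewise-constant
drive: ``v <- v*alpha + D*(1-alpha)`` with ``alpha = exp(-dt/tau)``, where D
is the total synaptic drive expressed directly in membrane (threshold)
units, i.e. the steady-state membrane value a constant drive would reach.
Synaptic channels decay exponentially per step and spikes deposit the edge
weight into the target's channel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lif_step_series", "run_network"]


@njit(cache=True)
def lif_step_series(drive, alpha, v_thr, v_reset, refrac_steps):
    """Integrate a per-sample drive series through one LIF neuron.

    Returns the sample indices at which spikes occur.
    """
    n = drive.shape[0]
    out = np.empty(n, dtype=np.int64)
    m = 0
    v = 0.0
    hold = 0
    for k in range(n):
        if hold > 0:
            hold -= 1
            v = v_reset
            continue
        v = v * alpha + drive[k] * (1.0 - alpha)
        if v >= v_thr:
            out[m] = k
            m += 1
            v = v_reset
            hold = refrac_steps
    return out[:m]


@njit(cache=True)
def run_network(nsteps, n_neurons,
                alpha_m, v_thr, v_reset, refrac_steps,
                beta_ch,
                indptr, targets, weights, channels,
                ext_steps, ext_units,
                max_events):
    """Clock-driven simulation of a recurrent LIF network.

    Units 0..n_neurons-1 are simulated neurons; higher unit indices are
    virtual external sources whose events arrive through ``ext_steps`` /
    ``ext_units`` (sorted by step).  The CSR adjacency (indptr, targets,
    weights, channels) covers all units.  Returns event steps, event neuron
    ids, an overflow flag (event budget exhausted -> runaway excitation),
    and per-neuron time-summed positive and negative synaptic drives for
    excitation/inhibition balance probes.
    """
    n_ch = beta_ch.shape[0]
    v = np.zeros(n_neurons)
    cur = np.zeros((n_ch, n_neurons))
    hold = np.zeros(n_neurons, dtype=np.int64)
    ev_step = np.empty(max_events, dtype=np.int64)
    ev_id = np.empty(max_events, dtype=np.int32)
    acc_pos = np.zeros(n_neurons)
    acc_neg = np.zeros(n_neurons)
    ne = 0
    p = 0
    n_ext = ext_steps.shape[0]
    for s in range(nsteps):
        while p < n_ext and ext_steps[p] == s:
            u = ext_units[p]
            for k in range(indptr[u], indptr[u + 1]):
                cur[channels[k], targets[k]] += weights[k]
            p += 1
        for c in range(n_ch):
            b = beta_ch[c]
            for i in range(n_neurons):
                cur[c, i] *= b
        for i in range(n_neurons):
            tot = 0.0
            for c in range(n_ch):
                x = cur[c, i]
                tot += x
                if x > 0.0:
                    acc_pos[i] += x
                else:
                    acc_neg[i] += x
            if hold[i] > 0:
                hold[i] -= 1
                v[i] = v_reset[i]
                continue
            a = alpha_m[i]
            v[i] = v[i] * a + tot * (1.0 - a)
            if v[i] >= v_thr[i]:
                if ne >= max_events:
                    return ev_step[:ne], ev_id[:ne], True, acc_pos, acc_neg
                ev_step[ne] = s
                ev_id[ne] = i
                ne += 1
                v[i] = v_reset[i]
                hold[i] = refrac_steps[i]
                for k in range(indptr[i], indptr[i + 1]):
                    cur[channels[k], targets[k]] += weights[k]
    return ev_step[:ne], ev_id[:ne], False, acc_pos, acc_neg
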