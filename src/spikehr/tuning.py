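"""Shipped synaptic-weight defaults for the decoder and state machines.

The studied parameter blocks fix population sizes and connection
probabilities but not synaptic efficacies.  The magnitudes below were found
by a grid search over candidate weights, accepting a setting when (i) a
single-winner steady state exists under band-dominant input, (ii) winner
population rates fall in the 20-40 Hz range, (iii) the winner agrees with
the rate-equation argmax oracle under 20% device mismatch, and — for the
gated state machines — (iv) an active state persists after its input is
removed while non-enabled states cannot ignite.  Weights are expressed in
membrane threshold units of steady-state drive (see ``network``).

Edit a copy of these dataclasses (or override via the run configuration)
to retune; they are versioned with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .preprocess import LIFParams

__all__ = ["StateMachineTuning", "DecoderTuning", "WEIGHTS", "DECODER_TUNING"]


@dataclass(frozen=True)
class StateMachineTuning:
    """Synaptic efficacies for one state-machine architecture.

    Excitatory (state and gate) neurons carry a long refractory period so
    active populations saturate near the 25-40 Hz operating range of the
    emulated hardware; inhibitory neurons keep a short refractory period so
    global inhibition scales super-linearly with the number of active
    states, which is what makes the competition winner-take-all rather
    than winner-share-all.
    """

    neuron: LIFParams = LIFParams(tau=0.02, v_thr=1.0, v_reset=0.0, refractory=0.025)
    inh_neuron: LIFParams = LIFParams(tau=0.02, v_thr=1.0, v_reset=0.0, refractory=0.003)
    #: gate (disinhibition-block) neurons carry a raised threshold so a gate
    #: only opens from a fully active driver state, never from the low-rate
    #: leak firing of a blocked state (which would otherwise self-ignite
    #: through its own gate)
    d_neuron: LIFParams = LIFParams(tau=0.02, v_thr=2.0, v_reset=0.0, refractory=0.025)
    w_ee: float = 0.046     # recurrent excitation within a state (slow)
    w_ei: float = 1.5       # state -> global inhibition (fast)
    w_ie: float = 0.5       # global inhibition -> state, magnitude (fast)
    w_ii: float = 0.2       # inhibition -> inhibition, magnitude (fast)
    w_in: float = 1.0       # per-edge weight of 16-source Poisson band input
    #: nominal Poisson rate of a fully driven band (input normalization target)
    input_rate_hz: float = 60.0
    # disinhibition blocks (gated architectures only)
    w_d_ee: float = 0.05
    w_d_ei: float = 1.0
    w_d_ie: float = 1.0
    w_d_ii: float = 0.2
    w_drive: float = 2.0    # state -> gate excitation (fast)
    w_gate: float = 0.065   # gate -> state excitation (slow, dense)


@dataclass(frozen=True)
class DecoderTuning:
    """Decoder-layer neuron and input scaling."""

    tau_m: float = 0.02
    refractory: float = 0.002
    syn_tau: float = 0.01
    w_total: float = 1.8    # per-neuron total pooled input weight


WEIGHTS = {
    # WTA: winners are sustained by their input, so recurrence and input are
    # strong and there is no gate system.
    "wta": StateMachineTuning(),
    # Gated machines: input alone must never flip or ignite a state (only
    # input + an open gate can), and a state must persist on its self-gate
    # after its input leaves, so recurrence is weak and gates carry the
    # persistence and transition drive.
    "nnnsm": StateMachineTuning(w_ee=0.08, w_ei=2.25, w_ie=0.5, w_in=0.4,
                                w_gate=0.055, w_drive=2.0),
    "mononsm": StateMachineTuning(w_ee=0.07, w_ei=2.25, w_ie=0.4, w_in=0.4,
                                  w_gate=0.05, w_drive=2.5),
}

DECODER_TUNING = DecoderTuning()
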