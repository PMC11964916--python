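# Methods

`spikehr` re-creates, in software, a neuromorphic processing chain for
photoplethysmography (PPG): heart rate is read out both as a continuous
estimate (a population decoder) and as a discrete zone with controlled
transition rules (spiking state machines), with accelerometer-assisted
artifact removal and a per-spike energy model of the emulated mixed-signal
chip. This note records the models, the parameters that matter, the choices
made where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Synthetic PPG

A single PPG pulse is the sum of two Gaussians placed on a circular phase
variable θ ∈ (−π, π]:

    z(t) = Σ_{i=1,2} a_i exp(−(θ(t) − θ_i)² / (2 b_i²)),
    θ(t) = atan2(sin ψ, cos ψ),  ψ(t) = ∫₀ᵗ ω(τ) dτ − φ(t₀) − π,

with ω = 2π·HR/60. Defaults (a₁=0.19, a₂=0.07, b₁=0.42, b₂=0.5,
θ₁=−0.7, θ₂=0.4, t₀=0.403 s) describe an average pulse fitted to clean
recordings. Because the phase is accumulated, step or ramp HR trajectories
never introduce phase discontinuities; for constant HR the signal is
periodic with period 60/HR. Gaussian distances are evaluated circularly so
pulses wrap seamlessly.

Two deliberate readings of ambiguous notation: the (x, y) pair is taken as
(cos ψ, sin ψ) so the phase point actually traces a circle, and b_i is used
directly as the Gaussian σ (the alternative 2b_i reading is available via
`PPGPulseSpec(width_is_two_sigma=True)`).

**Identifiability of the pulse fit.** The map (θ₁, θ₂, t₀) → z(·) has an
exact gauge freedom: shifting t₀ by δ and both centers by −ω·δ leaves the
waveform unchanged. `fit_pulse_params` therefore pins t₀ at the detected
inter-pulse trough (a self-consistent canonical gauge) and fits the six
shape parameters. Recovery should be judged on the identifiable content:
amplitudes, widths, the center separation θ₁−θ₂, and the joint phase
θ_i + ω·t₀. The profile's intrinsic minimum sits ≈0.026 rad away from ±π,
so individual θ values recovered in the trough gauge differ from any other
gauge's representatives by that constant.

**Noise.** Target noise power is P_signal·10^(−SNR/10). White Gaussian
noise is shaped in the frequency domain by scaling spectral amplitudes with
f^(α/2) (α = 0, −1, −2, +1, +2 for white, pink, brown, blue, violet; DC
zeroed) and then renormalized so the realized power equals the target
exactly, making SNR calibration deterministic rather than statistical.

## Signal-to-spike conversion

Each input is band-pass filtered into four HR bands (wide set 60–82, 82–105,
105–128, 128–150 bpm; narrow set 60–80, 80–88, 88–96, 96–150 bpm; edges in
Hz are bpm/60), full-wave rectified, amplified (default gain 8), and
injected into a leaky integrate-and-fire (LIF) neuron (τ = 24 ms, threshold
1, reset 0, no refractory period). Filters are causal Butterworth
(default order 2) implemented as second-order sections; zero-phase filtering
is deliberately not used — the chain must be runnable in real time.
Integration uses the exact exponential update per input sample, removing
step-size sensitivity at 125–256 Hz input rates.

Two normalizations make the stated operating point reachable for signals of
arbitrary scale: the pipeline rescales its input to unit RMS, and the
pipeline LIF uses a unit-DC-gain form dv/dt = (I − v)/τ, so a constant
input of amplitude A drives the membrane toward gain·A regardless of τ.
The plain form dv/dt = −v/τ + I (whose constant-current inter-spike
interval is τ·ln(Iτ/(Iτ − V_thr))) remains the default of the standalone
`lif_encode`. Without these normalizations, gain 8 on the two-Gaussian
pulse (peak ≈0.2) never reaches threshold 1.

With boundary filters enabled, one extra band is added below 60 and above
150 bpm (each one neighbor-width wide); their role is to anchor the decoder
at the edges of the HR range.

## Network simulator

Populations of LIF neurons with exponentially decaying synaptic currents
are integrated clock-driven (default dt = 0.1 ms; long experiments use
1 ms, which is ≥10 steps per fastest synaptic time constant). Synaptic
efficacies are expressed in membrane threshold units of steady-state drive:
a presynaptic rate r through weight w and synaptic τ_s contributes mean
drive w·r·τ_s. Connectivity is Bernoulli per (pre, post) pair with the
declared probability (no autapses), so in-degrees are binomial. Device
mismatch — the analog-hardware heterogeneity the original system must
tolerate — is emulated as multiplicative Gaussian jitter (CV configurable,
0.2 in the robustness experiments) on membrane time constants, thresholds,
and weights. Everything derives from one seed (connectivity, mismatch, and
Poisson inputs use independent child streams), so any run is bit-exactly
reproducible. A per-neuron event budget (default 1 kHz average) converts
runaway excitation into an explicit error instead of a silent saturation.

The WTA rate equations τ·dr_i/dt = −r_i + f(I_i − Σ_{j≠i} w_ij r_j) with
w_ij = γ·Θ(r_j − r_i) are integrated to steady state as an independent
oracle: for distinct inputs the unique survivor is argmax I_i; exact ties
raise a tie error rather than being broken arbitrarily (the spiking network
breaks ties through noise and mismatch).

## Decoder

Thirteen LIF neurons uniformly tile 60–150 bpm (7.5 bpm spacing). Neuron k
pools the six band spike trains with Gaussian weights
exp(−(c_k − β_j)²/2σ²) in bpm (σ = 2 neuron spacings), each row normalized
to a constant total weight (1.8) so edge neurons are not underdriven.
Off-line readout: per 2 s window (0.5 s step) the 13-neuron rate profile is
smoothed with a Gaussian kernel along the bpm axis (σ = 4 bpm) and the peak
position is interpolated quadratically; at the two edge neurons an
asymmetric three-point parabola is used (clipped to the HR range), because
a plain peak-at-edge readout pins everything near 60 or 150 bpm to the edge
center. Decoded values are attributed to input time t − 1.2 s, the mean
analytic group delay of the band filters at their centers — computed from
the filter design, not fitted to data.

The pooling and smoothing widths were calibrated once on clean constant-HR
synthetic data; the narrower textbook defaults (σ = 1 spacing, kernel
7.5 bpm) leave a strong within-band plateau and roughly double the error.
On the 470 s staircase (ten uniform levels 60→150 bpm) the order-2/gain-8
chain reaches ≈1.4 bpm RMSE end-to-end: ≈1.25 bpm of residual bias from
the maximally flat in-band response of the Butterworth bank (the peak
interpolation must work off the filter flanks alone) plus tracking-lag
windows at the ten steps. Order 2 clearly beats orders 1 and 4, confirming
that moderate inter-band leakage is what makes continuous interpolation
possible.

## State machines

All three architectures share a competition scaffold: four excitatory state
populations (16 neurons, one per HR band) and one global inhibitory
population (16 neurons), with the studied connection probabilities
(recurrent excitation 0.85/0.80, excitation→inhibition 0.40–0.45,
inhibition→excitation 0.45–0.50, inhibition→inhibition 0.20/0.50, inputs
0.30). The gated variants add one disinhibition block per state (16
excitatory + 4 inhibitory neurons, internal probabilities 0.5/0.3/0.3/0.5).

Synaptic weight magnitudes are not part of the published parameter block;
the shipped defaults (`tuning.py`) came from a grid search against a
behavioural battery (single winner in the 20–40 Hz zone, oracle agreement
under 20% mismatch, persistence, adjacency and monotonicity). Three
mechanisms proved load-bearing and are the package's own design:

1. **Asymmetric refractory periods.** Excitatory neurons carry a 25 ms
   refractory period, so active populations saturate near the operating
   rates of the emulated hardware; inhibitory neurons stay fast (3 ms), so
   global inhibition keeps headroom and grows super-linearly with the
   number of active states. That asymmetry — saturating excitation against
   non-saturating inhibition — is what makes the competition
   winner-take-all rather than winner-share-all.
2. **Gate wiring.** Each state's disinhibition block projects dense slow
   excitation back onto its state ("opening the gate"). In the
   nearest-neighbor machine a state drives its own gate (probability 1.0)
   and its neighbors' gates (0.5); in the monotonic machine a state drives
   only the next-higher gate (1.0) and its own at 0.5. Input alone can
   never ignite a state against an active competitor's inhibition; input
   plus an open gate can; the self-gate loop keeps a state alive after its
   input leaves (the network remembers its band instead of collapsing).
   The allowed-transition matrix is therefore tridiagonal for the
   nearest-neighbor machine and upper-bidiagonal for the monotonic one.
3. **Raised gate thresholds.** Gate neurons carry threshold 2 (states: 1),
   so a gate opens only for a fully active driver state. Without this, the
   low-rate leak firing of a blocked state would open its own gate and the
   dense gate feedback would amplify the leak into a full ignition —
   precisely the non-adjacent jumps the architecture exists to forbid.

Slow synapses (100 ms) carry recurrent excitation and the gate feedback,
giving the attractors their hundreds-of-milliseconds integration scale;
fast synapses (10 ms) carry inhibition and feed-forward input.

The state machines are driven from the decoder layer: decoder neurons whose
centers fall in a band are merged into that band's input train. Compared to
feeding the raw band encoders, the Gaussian pooling suppresses the pulse
waveform's second harmonic, which otherwise leaks into the upper bands
(e.g. at 71 bpm the 2.37 Hz harmonic lands in the 128–150 bpm band at ~60%
of the fundamental's rate) and can flip the winner on unlucky wiring seeds
— an effect the original study also attributes its upper-band errors to.
Band drives are converted to per-window Poisson rates normalized so the
strongest band maps to 60 Hz, the input operating point the weights were
tuned at; windows with a maximal band rate below 1 Hz produce no drive.

Transition-time measurement: the network settles into one state (Poisson
input at 60 Hz, kept running), a second band is stimulated at a varying
rate, and the reported time is the first sustained (≥0.5 s) crossing of the
two population rates. The resulting curve is a sharp ignition threshold in
the stimulation rate with graded, seed-dependent times near threshold —
monotone non-increasing in the rate on every seed tested.

## Artifact removal

The four band-filtered PPG channels and twelve band-filtered accelerometer
channels (three axes × four bands; every source normalized to unit RMS) are
combined per band as

    combined_b = w_b·PPG_b + Σ_axis w[axis, b]·accel[axis, b],

i.e. each accelerometer coefficient corrects its own band. (Adding one
shared broadband accelerometer correction to every band was considered and
rejected: it cannot cancel a band-limited leak exactly and injects
out-of-band motion into every encoder.) The objective pushes each combined
band through rectification and the LIF encoder and compares 2 s / 0.5 s
firing-rate series against ECG-derived reference rates: per-band RMSE
normalized by the grand-mean reference rate (per-band normalization would
explode on near-silent bands), averaged.

Optimization is Nelder-Mead from a raw-PPG start (PPG coefficients 1,
accelerometer 0) plus seeded uniform(−1,1) restarts, with an explicit
initial simplex (steps 0.1/0.25) because the default simplex never moves
coefficients that start at zero. The operation's default of 20 iterations
mirrors the original description, but 20 simplex iterations cannot traverse
a 16-dimensional space; the tests and fixtures use 400 iterations and 3
restarts, which on the known-mixture fixture halves the objective and
recovers the corrupted axis's summed coefficient with the correct sign.

The motion fixture is fully synthetic (and labelled so): clean synthetic
PPG doubles as the ECG surrogate, the three accelerometer axes are
band-limited (1.4–1.9 Hz) Gaussian motion, and corruption adds a known
multiple of one axis. Group-specific corruption (different axes/signs per
"exercise") lets per-group fits beat a global fit, mirroring the finding
that tailored calibration helps.

## Power model

P = Σ_n r_n·(E_spike + E_enc + N_cores·(E_br + E_rt) + N_cam_match·E_pulse)
with the 1.8 V per-operation energies E_spike = E_enc = 883 pJ,
E_br = 6.84 nJ, E_rt = 360 pJ, E_pulse = 324 pJ. One neuron at 1 Hz with one
destination core and no postsynaptic matches dissipates 8.966 nW. Energy is
power × duration; battery energy is V × mAh × 3.6 J. The published
subsystem powers cannot be recomputed without the unstated per-neuron
routing fan-out, so `calibrate_fanout` reports the N_cam_match that
reconciles a measured mean rate with a given power (e.g. ≈25 Hz × 16
neurons ↔ 61.6 μW at N_cam_match ≈ 146), and rasters can be costed with
their realized fan-out.

## Problem sizes and reproducibility

Default experiment sizes: decoder runs use the full 470 s staircase at
125 Hz (≈1 s of compute per run after JIT warm-up); noise-robustness trials
are 100 s staircases through the four band centers, 10 seeds per condition;
WTA/oracle agreement uses 100 four-second trials; state-machine invariant
runs are 22–32 s. Simulations for the state machines use dt = 1 ms, the
single-neuron and balance checks 0.1–0.5 ms. All randomness flows from
explicit seeds; `run_experiment` embeds the config digest and seed in every
output file and reproduces a run directory bit-for-bit.

## Limitations

* The synthetic generator emulates pulse morphology, HR dynamics and
  calibrated sensor noise — not respiration, baseline wander, dicrotic
  physiology beyond the two-Gaussian shape, or optical sensor effects.
  Passing tests demonstrate the architecture's mechanics, not clinical
  accuracy on real recordings.
* Decoder accuracy on the synthetic staircase is ≈1.4 bpm end-to-end
  against the ~1 bpm reported for the original system; the residual is a
  structural bias of continuous peak interpolation over a maximally flat
  filter bank plus step-transition lag (see the decoder section).
* Neurons are plain LIF rather than the adaptive-exponential circuits of
  the physical chip; weight magnitudes are tuned for this model, and the
  published connection probabilities are kept verbatim.
* Real-dataset loaders are generic delimited-text readers; the wrist and
  bedside monitoring datasets used by the original study are not required
  or downloaded, and hardware-specific behaviours (address-event routing,
  state retention across power cycles) are out of scope.
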