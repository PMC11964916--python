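"""Builders and readouts for the four studied networks.

* **HR decoder** — 13 LIF neurons tiling 60–150 bpm, each pooling the six
  band spike trains (4 HR bands + 2 boundary bands) through Gaussian
  weights of the bpm distance between the neuron's center and the band's
  center.  Off-line readout smooths the 13-neuron rate profile along the
  bpm axis and returns the interpolated peak position as the decoded HR.
* **Soft WTA** — four excitatory populations (one per HR band) competing
  through one global inhibitory population; selects the most active band.
* **Nearest-neighbor NSM** — the WTA scaffold plus one disinhibition E-I
  block per state.  A state's activity opens only the gates of its adjacent
  states, so transitions are restricted to neighboring HR bands; each state
  also drives its own gate, which keeps it active when its input leaves
  (the network "remembers" the band rather than jumping).
* **Monotonic NSM** — same scaffold with asymmetric gate feedback: a state
  opens only the gate of the next-higher band, enforcing a unidirectional
  progression through HR zones.

Population sizes and all connection probabilities follow the studied
parameter blocks (see WTA_PARAMS / NNNSM_PARAMS / MONONSM_PARAMS); synaptic
weight magnitudes are not part of those blocks and ship as tuned defaults
(see ``tuning.py``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import (FilterBankConfig, LIFParams, SpikeTrain, WIDE_BANDS,
                         preprocess_pipeline)
from .network import (ConnectionSpec, NetworkSpec, PoissonInput, PopulationSpec,
                      SpikeRaster, SpikeTrainInput, SLOW_TAU, FAST_TAU,
                      population_rate, simulate)
from .tuning import DecoderTuning, StateMachineTuning, DECODER_TUNING, WEIGHTS

__all__ = [
    "DecoderConfig",
    "StateMachineParams",
    "WTA_PARAMS",
    "NNNSM_PARAMS",
    "MONONSM_PARAMS",
    "StateTrace",
    "build_decoder",
    "decoder_weight_matrix",
    "run_decoder",
    "decode_hr",
    "decode_hr_series",
    "build_wta",
    "build_nnnsm",
    "build_mononsm",
    "build_state_machine",
    "drive_state_machine",
    "read_state",
    "measure_transition_time",
    "disinh_adjacency",
]

STATE_LABELS = ("e1", "e2", "e3", "e4")


# ---------------------------------------------------------------------------
# parameter blocks (population sizes and connection probabilities)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateMachineParams:
    """Population sizes and connection probabilities for one architecture.

    Per-band entries are ordered e1..e4.  Disinhibition entries are None
    for the plain WTA.
    """

    kind: str
    n_exc: tuple[int, int, int, int] = (16, 16, 16, 16)
    n_inh: int = 16
    n_exc_disinh: int | None = None
    n_inh_disinh: int | None = None
    p_exc_exc: tuple[float, ...] = (0.85, 0.85, 0.85, 0.85)
    p_exc_inh: tuple[float, ...] = (0.40, 0.40, 0.40, 0.40)
    p_inh_exc: tuple[float, ...] = (0.50, 0.50, 0.50, 0.50)
    p_inh_inh: float = 0.20
    p_inp: tuple[float, ...] = (0.30, 0.30, 0.30, 0.30)
    p_d_exc_exc: float | None = None
    p_d_exc_inh: float | None = None
    p_d_inh_exc: float | None = None
    p_d_inh_inh: float | None = None
    p_ex_disinh: float | None = None
    p_disinh_ex: float | None = None
    p_ex_disinh0: float | None = None

    @property
    def has_disinhibition(self) -> bool:
        return self.n_exc_disinh is not None

    def require(self, key: str):
        v = getattr(self, key)
        if v is None:
            raise ValueError(f"parameter block for {self.kind!r} is missing {key!r}")
        return v


WTA_PARAMS = StateMachineParams(
    kind="wta",
    p_exc_exc=(0.85, 0.85, 0.85, 0.85),
    p_exc_inh=(0.40, 0.40, 0.40, 0.40),
    p_inh_exc=(0.50, 0.45, 0.50, 0.50),
    p_inh_inh=0.20,
)

NNNSM_PARAMS = StateMachineParams(
    kind="nnnsm",
    n_exc_disinh=16, n_inh_disinh=4,
    p_exc_exc=(0.85, 0.85, 0.85, 0.80),
    p_exc_inh=(0.40, 0.45, 0.40, 0.40),
    p_inh_exc=(0.50, 0.50, 0.50, 0.50),
    p_inh_inh=0.20,
    p_d_exc_exc=0.50, p_d_exc_inh=0.30, p_d_inh_exc=0.30, p_d_inh_inh=0.50,
    p_ex_disinh=0.50, p_disinh_ex=1.0, p_ex_disinh0=1.0,
)

MONONSM_PARAMS = StateMachineParams(
    kind="mononsm",
    n_exc_disinh=16, n_inh_disinh=4,
    p_exc_exc=(0.85, 0.85, 0.85, 0.80),
    p_exc_inh=(0.40, 0.45, 0.40, 0.40),
    p_inh_exc=(0.50, 0.50, 0.45, 0.50),
    p_inh_inh=0.50,
    p_d_exc_exc=0.50, p_d_exc_inh=0.30, p_d_inh_exc=0.30, p_d_inh_inh=0.50,
    p_ex_disinh=1.0, p_disinh_ex=1.0, p_ex_disinh0=0.5,
)

_PARAMS = {"wta": WTA_PARAMS, "nnnsm": NNNSM_PARAMS, "mononsm": MONONSM_PARAMS}


def params_to_config(params: StateMachineParams) -> dict:
    """Flatten a parameter block into the conventional key-value naming
    (n_exc0.., p_exc_exc_ex0.., p_inp_ex0.., p_ex_disinh..)."""
    out = {"kind": params.kind}
    for i in range(4):
        out[f"n_exc{i}"] = params.n_exc[i]
        out[f"p_exc_exc_ex{i}"] = params.p_exc_exc[i]
        out[f"p_exc_inh_ex{i}"] = params.p_exc_inh[i]
        out[f"p_inh_exc_ex{i}"] = params.p_inh_exc[i]
        out[f"p_inp_ex{i}"] = params.p_inp[i]
    out["n_inh"] = params.n_inh
    out["p_inh_inh"] = params.p_inh_inh
    if params.has_disinhibition:
        out["n_exc_disinh"] = params.n_exc_disinh
        out["n_inh_disinh"] = params.n_inh_disinh
        out["p_exc_exc_disinh"] = params.p_d_exc_exc
        out["p_exc_inh_disinh"] = params.p_d_exc_inh
        out["p_inh_exc_disinh"] = params.p_d_inh_exc
        out["p_inh_inh_disinh"] = params.p_d_inh_inh
        out["p_ex_disinh"] = params.p_ex_disinh
        out["p_disinh_ex"] = params.p_disinh_ex
        out["p_ex_disinh0"] = params.p_ex_disinh0
    return out


def params_from_config(cfg: dict) -> StateMachineParams:
    """Rebuild a parameter block from the flat key-value form."""
    cfg = dict(cfg)
    kind = cfg.pop("kind")
    kw = dict(
        kind=kind,
        n_exc=tuple(cfg.pop(f"n_exc{i}") for i in range(4)),
        p_exc_exc=tuple(cfg.pop(f"p_exc_exc_ex{i}") for i in range(4)),
        p_exc_inh=tuple(cfg.pop(f"p_exc_inh_ex{i}") for i in range(4)),
        p_inh_exc=tuple(cfg.pop(f"p_inh_exc_ex{i}") for i in range(4)),
        p_inp=tuple(cfg.pop(f"p_inp_ex{i}") for i in range(4)),
        n_inh=cfg.pop("n_inh"),
        p_inh_inh=cfg.pop("p_inh_inh"),
    )
    rename = {"p_exc_exc_disinh": "p_d_exc_exc", "p_exc_inh_disinh": "p_d_exc_inh",
              "p_inh_exc_disinh": "p_d_inh_exc", "p_inh_inh_disinh": "p_d_inh_inh",
              "n_exc_disinh": "n_exc_disinh", "n_inh_disinh": "n_inh_disinh",
              "p_ex_disinh": "p_ex_disinh", "p_disinh_ex": "p_disinh_ex",
              "p_ex_disinh0": "p_ex_disinh0"}
    for key, field_name in rename.items():
        if key in cfg:
            kw[field_name] = cfg.pop(key)
    if cfg:
        raise ValueError(f"unknown parameter keys {sorted(cfg)}")
    return StateMachineParams(**kw)


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoderConfig:
    """Configuration of the 13-neuron HR decoder layer.

    Decoder neurons uniformly tile ``hr_range``; ``sigma_spacing`` is the
    width of the Gaussian input pooling in units of the neuron spacing,
    ``kernel_sigma_bpm`` the width of the off-line smoothing kernel applied
    along the bpm axis before peak detection.
    """

    n_neurons: int = 13
    hr_range: tuple[float, float] = (60.0, 150.0)
    sigma_spacing: float = 2.0
    kernel_sigma_bpm: float = 4.0
    window: float = 2.0
    step: float = 0.5
    #: decode latency: decoded values are attributed to input time
    #: t_window_center - latency.  None computes the mean analytic group
    #: delay of the band filters at their center frequencies.
    latency: float | None = None
    filter_bank: FilterBankConfig = field(
        default_factory=lambda: FilterBankConfig(bands=WIDE_BANDS, order=2, gain=8.0,
                                                 include_boundary=True))
    tuning: DecoderTuning = DECODER_TUNING

    def __post_init__(self):
        if self.n_neurons < len(self.filter_bank.all_bands):
            raise ValueError("decoder layer must be at least as large as the band count")
        if self.hr_range[1] <= self.hr_range[0]:
            raise ValueError("hr_range must be increasing")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.hr_range[0], self.hr_range[1], self.n_neurons)

    def group_delay(self, fs: float = 125.0) -> float:
        """Mean analytic group delay (s) of the band filters at their centers."""
        import warnings

        from scipy import signal as sps
        gds = []
        for band in self.filter_bank.all_bands:
            sos = sps.butter(self.filter_bank.order, [band.low_hz, band.high_hz],
                             btype="bandpass", fs=fs, output="sos")
            b, a = sps.sos2tf(sos)
            with warnings.catch_warnings():
                # narrow bands at ~1 Hz of 125 Hz put poles near z=1; the
                # delay evaluated at the band center is still well-defined
                warnings.simplefilter("ignore")
                _, gd = sps.group_delay((b, a), w=[band.center_bpm / 60.0], fs=fs)
            gds.append(gd[0] / fs)
        return float(np.mean(gds))

    @property
    def spacing(self) -> float:
        return (self.hr_range[1] - self.hr_range[0]) / (self.n_neurons - 1)


def decoder_weight_matrix(cfg: DecoderConfig) -> np.ndarray:
    """Gaussian pooling weights, shape (n_neurons, n_bands).

    ``W[k, j] ∝ exp(-(c_k - beta_j)^2 / (2 sigma^2))`` with the neuron
    centers ``c`` and band centers ``beta`` in bpm; each neuron row is
    normalized to a constant total input weight so edge neurons are not
    underdriven.
    """
    centers = cfg.centers
    betas = np.array([b.center_bpm for b in cfg.filter_bank.all_bands])
    sigma = max(cfg.sigma_spacing * cfg.spacing, 1e-9)
    W = np.exp(-((centers[:, None] - betas[None, :]) ** 2) / (2.0 * sigma**2))
    if cfg.sigma_spacing <= 0:  # delta limit: nearest band only
        W = np.zeros_like(W)
        W[np.arange(cfg.n_neurons), np.argmin(
            np.abs(centers[:, None] - betas[None, :]), axis=1)] = 1.0
    W = W / W.sum(axis=1, keepdims=True) * cfg.tuning.w_total
    return W


def build_decoder(cfg: DecoderConfig | None = None) -> NetworkSpec:
    """Network spec of the decoder layer (13 LIF neurons, no recurrence)."""
    if cfg is None:
        cfg = DecoderConfig()
    lif = LIFParams(tau=cfg.tuning.tau_m, v_thr=1.0, v_reset=0.0,
                    refractory=cfg.tuning.refractory)
    return NetworkSpec([PopulationSpec("dec", cfg.n_neurons, "excitatory", lif)], [])


def run_decoder(band_trains: list[SpikeTrain], cfg: DecoderConfig | None = None,
                duration: float | None = None, seed: int = 0,
                mismatch_cv: float = 0.0, dt: float = 1e-3) -> SpikeRaster:
    """Drive the decoder layer with the per-band spike trains."""
    if cfg is None:
        cfg = DecoderConfig()
    W = decoder_weight_matrix(cfg)
    if len(band_trains) != W.shape[1]:
        raise ValueError(f"expected {W.shape[1]} band trains, got {len(band_trains)}")
    if duration is None:
        duration = max((float(t.times[-1]) if len(t) else 0.0) for t in band_trains)
    spec = build_decoder(cfg)
    spec.mismatch_cv = mismatch_cv
    spec.seed = seed
    inputs = {"dec": [SpikeTrainInput(tr, weight=W[:, j], synapse_tau=cfg.tuning.syn_tau)
                      for j, tr in enumerate(band_trains)]}
    return simulate(spec, inputs, duration=duration, dt=dt, seed=seed)


def _smooth_profile(rates: np.ndarray, cfg: DecoderConfig) -> np.ndarray:
    centers = cfg.centers
    K = np.exp(-((centers[:, None] - centers[None, :]) ** 2)
               / (2.0 * max(cfg.kernel_sigma_bpm, 1e-9) ** 2))
    K /= K.sum(axis=1, keepdims=True)
    return K @ rates


def decode_hr(rates: np.ndarray, cfg: DecoderConfig | None = None) -> float:
    """Decode one HR value (bpm) from a 13-neuron rate profile.

    Smooths the profile with a Gaussian kernel over the bpm axis and
    returns the continuous argmax position via quadratic interpolation
    around the peak.  Returns NaN for an all-zero profile.
    """
    if cfg is None:
        cfg = DecoderConfig()
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (cfg.n_neurons,):
        raise ValueError(f"expected {cfg.n_neurons} rates")
    if not np.any(rates > 0):
        return float("nan")
    prof = _smooth_profile(rates, cfg)
    m = int(np.argmax(prof))
    last = len(prof) - 1
    if m == 0 or m == last:
        # peak at the range edge: fit the parabola through the three
        # outermost points and take its vertex if it falls just outside
        idx = (0, 1, 2) if m == 0 else (last - 2, last - 1, last)
        a, b, c3 = prof[idx[0]], prof[idx[1]], prof[idx[2]]
        denom = a - 2 * b + c3
        if denom < 0:
            x = idx[1] + 0.5 * (a - c3) / denom  # vertex in neuron units
            x = float(np.clip(x, 0.0, float(last)))  # never outside the HR range
            if (m == 0 and x <= 1.0) or (m == last and x >= last - 1):
                return float(cfg.centers[0] + x * cfg.spacing)
        return float(cfg.centers[m])
    denom = prof[m - 1] - 2 * prof[m] + prof[m + 1]
    delta = 0.0 if denom == 0 else 0.5 * (prof[m - 1] - prof[m + 1]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(cfg.centers[m] + delta * cfg.spacing)


def decode_hr_series(raster: SpikeRaster, cfg: DecoderConfig | None = None):
    """Sliding-window HR decoding: returns (times, HR bpm).

    Times are window centers shifted back by the decode latency (the causal
    filter bank's group delay), so the decoded series is aligned with the
    input time axis.
    """
    if cfg is None:
        cfg = DecoderConfig()
    latency = cfg.latency if cfg.latency is not None else cfg.group_delay()
    lo, hi = raster.pop_slices["dec"]
    t_ids = raster.ids - lo
    starts = np.arange(0.0, raster.duration - cfg.window + 1e-12, cfg.step)
    hr = np.empty(len(starts))
    order = np.argsort(raster.times, kind="stable")
    times = raster.times[order]
    ids = t_ids[order]
    for i, s in enumerate(starts):
        a, b = np.searchsorted(times, (s, s + cfg.window))
        counts = np.bincount(ids[a:b], minlength=cfg.n_neurons).astype(float)
        hr[i] = decode_hr(counts / cfg.window, cfg)
    return starts + cfg.window / 2.0 - latency, hr


# ---------------------------------------------------------------------------
# state machines
# ---------------------------------------------------------------------------

def disinh_adjacency(params: StateMachineParams) -> np.ndarray:
    """Allowed state-transition matrix implied by the gate wiring.

    Entry (i, j) is True when a transition from state i to state j is
    enabled by a gate that state i's activity opens (plus the trivial
    self-transition).
    """
    A = np.eye(4, dtype=bool)
    if not params.has_disinhibition:
        return np.ones((4, 4), dtype=bool)
    for i in range(4):
        if params.kind == "mononsm":
            if i + 1 < 4:
                A[i, i + 1] = True
        else:
            if i - 1 >= 0:
                A[i, i - 1] = True
            if i + 1 < 4:
                A[i, i + 1] = True
    return A


def _gate_drivers(params: StateMachineParams, gate: int) -> list[tuple[int, float]]:
    """(state index, probability) pairs of states that open gate ``gate``."""
    out = []
    if params.kind == "mononsm":
        if gate - 1 >= 0:
            out.append((gate - 1, params.require("p_ex_disinh")))
        out.append((gate, params.require("p_ex_disinh0")))
    else:
        for nb in (gate - 1, gate + 1):
            if 0 <= nb < 4:
                out.append((nb, params.require("p_ex_disinh")))
        out.append((gate, params.require("p_ex_disinh0")))
    return out


def build_state_machine(params: StateMachineParams,
                        weights: StateMachineTuning | None = None,
                        mismatch_cv: float = 0.0, seed: int = 0) -> NetworkSpec:
    """Realizable network spec for a WTA / nnNSM / monoNSM block."""
    if weights is None:
        weights = WEIGHTS[params.kind]
    lif = replace(weights.neuron)
    lif_inh = replace(weights.inh_neuron)
    pops = [PopulationSpec(STATE_LABELS[i], params.n_exc[i], "excitatory", lif)
            for i in range(4)]
    pops.append(PopulationSpec("inh", params.n_inh, "inhibitory", lif_inh))
    conns: list[ConnectionSpec] = []
    for i, e in enumerate(STATE_LABELS):
        conns.append(ConnectionSpec(e, e, params.p_exc_exc[i], weights.w_ee, SLOW_TAU))
        conns.append(ConnectionSpec(e, "inh", params.p_exc_inh[i], weights.w_ei, FAST_TAU))
        conns.append(ConnectionSpec("inh", e, params.p_inh_exc[i], -abs(weights.w_ie), FAST_TAU))
    conns.append(ConnectionSpec("inh", "inh", params.p_inh_inh, -abs(weights.w_ii), FAST_TAU))

    if params.has_disinhibition:
        nd_e = params.require("n_exc_disinh")
        nd_i = params.require("n_inh_disinh")
        for g in range(4):
            de, di = f"d{g}", f"d{g}_inh"
            pops.append(PopulationSpec(de, nd_e, "excitatory", replace(weights.d_neuron)))
            pops.append(PopulationSpec(di, nd_i, "inhibitory", lif_inh))
            conns.append(ConnectionSpec(de, de, params.require("p_d_exc_exc"),
                                        weights.w_d_ee, FAST_TAU))
            conns.append(ConnectionSpec(de, di, params.require("p_d_exc_inh"),
                                        weights.w_d_ei, FAST_TAU))
            conns.append(ConnectionSpec(di, de, params.require("p_d_inh_exc"),
                                        -abs(weights.w_d_ie), FAST_TAU))
            conns.append(ConnectionSpec(di, di, params.require("p_d_inh_inh"),
                                        -abs(weights.w_d_ii), FAST_TAU))
            # gate output: dense slow excitation onto its state
            conns.append(ConnectionSpec(de, STATE_LABELS[g], params.require("p_disinh_ex"),
                                        weights.w_gate, SLOW_TAU))
            # gate drive from the states that open this gate
            for st, p in _gate_drivers(params, g):
                conns.append(ConnectionSpec(STATE_LABELS[st], de, p,
                                            weights.w_drive, FAST_TAU))
    return NetworkSpec(pops, conns, mismatch_cv=mismatch_cv, seed=seed)


def build_wta(params: StateMachineParams = WTA_PARAMS, **kw) -> NetworkSpec:
    if params.has_disinhibition:
        raise ValueError("WTA takes a parameter block without disinhibition populations")
    return build_state_machine(params, **kw)


def build_nnnsm(params: StateMachineParams = NNNSM_PARAMS, **kw) -> NetworkSpec:
    if params.kind != "nnnsm":
        raise ValueError("expected an nnNSM parameter block")
    return build_state_machine(params, **kw)


def build_mononsm(params: StateMachineParams = MONONSM_PARAMS, **kw) -> NetworkSpec:
    if params.kind != "mononsm":
        raise ValueError("expected a monoNSM parameter block")
    return build_state_machine(params, **kw)


def band_rate_profiles(band_trains, duration: float, window: float = 1.0) -> np.ndarray:
    """Windowed firing rates of the four band spike trains, shape (4, n_win)."""
    edges = np.arange(0.0, duration + 1e-12, window)
    n_win = max(len(edges) - 1, 1)
    out = np.zeros((4, n_win))
    for b, tr in enumerate(band_trains):
        t = tr.times if isinstance(tr, SpikeTrain) else np.asarray(tr, dtype=float)
        c = np.searchsorted(t, edges)
        out[b] = np.diff(c) / window
    return out


def trains_to_band_drives(band_trains, duration: float,
                          weights: StateMachineTuning, window: float = 1.0,
                          min_rate: float = 1.0) -> np.ndarray:
    """Normalize band spike trains into Poisson drive rates per window.

    The state machines operate at a tuned input operating point, so the raw
    encoder rates (whose absolute scale depends on signal amplitude) are
    rescaled per window: the maximal band maps to ``weights.input_rate_hz``
    and the others keep their relative strength.  Windows whose maximal
    band rate is below ``min_rate`` produce no drive.  Returns (4, n_win)
    Poisson rates.
    """
    prof = band_rate_profiles(band_trains, duration, window)
    mx = prof.max(axis=0)
    scale = np.where(mx >= min_rate, weights.input_rate_hz / np.maximum(mx, 1e-12), 0.0)
    return prof * scale[None, :]


def _piecewise_poisson(rng, rates, window, duration):
    """Event times of an inhomogeneous Poisson process with per-window rates."""
    times = []
    for k, r in enumerate(rates):
        if r <= 0:
            continue
        t0 = k * window
        n = rng.poisson(r * min(window, duration - t0))
        if n:
            times.append(t0 + rng.random(n) * min(window, duration - t0))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def drive_state_machine(spec: NetworkSpec, band_inputs, duration: float,
                        params: StateMachineParams | None = None,
                        weights: StateMachineTuning | None = None,
                        dt: float = 1e-3, seed: int = 0,
                        rate_window: float = 1.0,
                        rate_cap: float = 500.0) -> SpikeRaster:
    """Simulate a state machine driven per band.

    ``band_inputs`` is a length-4 sequence whose entries are either spike
    trains (from the preprocessing pipeline) or constant Poisson rates in
    Hz.  Spike trains are converted to normalized per-window Poisson drive
    (see :func:`trains_to_band_drives`); constant rates are used as given.
    """
    kind = spec_kind(spec)
    if weights is None:
        weights = WEIGHTS[kind]
    if params is None:
        params = _PARAMS[kind]
    if len(band_inputs) != 4:
        raise ValueError("expected one input per band (4)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 914]).generate_state(1)[0])
    is_train = [not (inp is None or isinstance(inp, (int, float))) for inp in band_inputs]
    inputs: dict[str, list] = {}
    if any(is_train):
        trains = [band_inputs[b] if is_train[b] else SpikeTrain(np.empty(0))
                  for b in range(4)]
        drives = trains_to_band_drives(trains, duration, weights, rate_window)
        for b in range(4):
            if not is_train[b]:
                continue
            srcs = [SpikeTrainInput(_piecewise_poisson(rng, drives[b], rate_window, duration),
                                    weight=weights.w_in, probability=params.p_inp[b])
                    for _ in range(16)]
            inputs.setdefault(STATE_LABELS[b], []).extend(srcs)
    for b, inp in enumerate(band_inputs):
        if isinstance(inp, (int, float)) and inp > 0:
            inputs.setdefault(STATE_LABELS[b], []).append(PoissonInput(
                rate=float(inp), weight=weights.w_in,
                probability=params.p_inp[b], n_sources=16))
    return simulate(spec, inputs, duration=duration, dt=dt, seed=seed, rate_cap=rate_cap)


def spec_kind(spec: NetworkSpec) -> str:
    names = {p.name for p in spec.populations}
    if "d0" not in names:
        return "wta"
    mono_forward = any(c.source == "e1" and c.target == "d1" for c in spec.connections)
    nn_backward = any(c.source == "e2" and c.target == "d0" for c in spec.connections)
    return "nnnsm" if nn_backward else ("mononsm" if mono_forward else "nnnsm")


@dataclass
class StateTrace:
    """Windowed decoded state sequence: per window one of e1..e4 or none."""

    times: np.ndarray            # window centers (s)
    state_index: np.ndarray      # 0..3, or -1 for none
    rates: np.ndarray            # (n_windows, 4) per-band rates (Hz/neuron)

    @property
    def labels(self) -> list[str]:
        return [STATE_LABELS[i] if i >= 0 else "none" for i in self.state_index]

    def active_sequence(self) -> np.ndarray:
        """Decoded state indices with 'none' windows dropped."""
        return self.state_index[self.state_index >= 0]


def read_state(raster: SpikeRaster, window: float = 0.5,
               margin: float = 0.1) -> StateTrace:
    """Windowed winner readout over the four excitatory state populations.

    Per window the state with the maximal population rate wins, provided it
    exceeds the runner-up by ``margin`` (a fraction of the winner's rate);
    otherwise the window is labelled none.  ``margin=0`` degenerates to a
    pure argmax (with all-silent windows still labelled none).
    """
    series = []
    for name in STATE_LABELS:
        t, r = population_rate(raster, name, window, window)
        series.append(r)
    rates = np.stack(series, axis=1)
    idx = np.argmax(rates, axis=1)
    win = rates[np.arange(len(idx)), idx]
    sorted_r = np.sort(rates, axis=1)
    runner = sorted_r[:, -2]
    ok = (win > 0) & (win - runner >= margin * win)
    out = np.where(ok, idx, -1)
    return StateTrace(t, out, rates)


def measure_transition_time(spec: NetworkSpec, settled_state: int, new_band: int,
                            input_rate: float, settle_rate: float = 60.0,
                            settle_time: float = 4.0, trial_time: float = 12.0,
                            dt: float = 1e-3, seed: int = 0,
                            window: float = 0.25, sustain: float = 0.5) -> float:
    """Time for a newly stimulated band to overtake the settled one.

    The network is first driven into ``settled_state`` with a Poisson input
    at ``settle_rate``, which keeps running for the whole trial; at the
    switch ``new_band`` is additionally stimulated at ``input_rate`` and
    must out-compete the incumbent.  Returns the first time (relative to
    the switch) at which the stimulated population's rate exceeds the
    previously active population's rate, or ``inf`` if that never happens
    within the trial.
    """
    for b in (settled_state, new_band):
        if not 0 <= b < 4:
            raise ValueError(f"band index {b} out of range 0..3")
    kind = spec_kind(spec)
    weights = WEIGHTS[kind]
    params = _PARAMS[kind]
    rng = np.random.default_rng(seed)

    def gated(rate, t0, t1):
        if rate <= 0 or t1 <= t0:
            return np.empty(0)
        n = int(rate * (t1 - t0) * 2 + 8 * np.sqrt(rate * (t1 - t0)) + 16)
        t = t0 + np.cumsum(rng.exponential(1.0 / rate, n))
        return t[t < t1]

    duration = settle_time + trial_time
    inputs = {
        STATE_LABELS[settled_state]: [
            SpikeTrainInput(gated(settle_rate, 0.0, duration),
                            weight=weights.w_in,
                            probability=params.p_inp[settled_state])
            for _ in range(16)],
    }
    new_trains = [SpikeTrainInput(gated(input_rate, settle_time, duration),
                                  weight=weights.w_in,
                                  probability=params.p_inp[new_band])
                  for _ in range(16)]
    key = STATE_LABELS[new_band]
    inputs.setdefault(key, []).extend(new_trains)
    raster = simulate(spec, inputs, duration=duration, dt=dt, seed=seed)
    t_old, r_old = population_rate(raster, STATE_LABELS[settled_state], window, window)
    _, r_new = population_rate(raster, STATE_LABELS[new_band], window, window)
    after = t_old > settle_time
    crossed = after & (r_new > r_old)
    # require the takeover to be sustained, not a transient noise crossing
    need = max(int(round(sustain / window)), 1)
    run_len = 0
    for i, c in enumerate(crossed):
        run_len = run_len + 1 if c else 0
        if run_len >= need:
            return float(t_old[i - need + 1] - settle_time)
    return float("inf")
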