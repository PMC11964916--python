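"""Signal-to-spike conversion: band-pass filter bank, rectification, LIF encoding.

An input waveform is split into heart-rate bands by causal Butterworth
band-pass filters (band edges stated in bpm, converted to Hz by /60), each
band is full-wave rectified and amplified, and the result is injected as a
time-varying current into a leaky integrate-and-fire neuron which emits one
spike train per band.

Two studied band sets are provided: a wide set covering 60–150 bpm in four
bands and a narrow set that refines the 80–96 bpm region.  With the boundary
flag enabled, one extra band is added below the first and above the last
band (same width as its neighbor) to stabilize decoding at the range edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import Waveform

__all__ = [
    "BandSpec",
    "FilterBankConfig",
    "LIFParams",
    "SpikeTrain",
    "WIDE_BANDS",
    "NARROW_BANDS",
    "make_filter_bank",
    "apply_filter_bank",
    "rectify_amplify",
    "lif_encode",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class BandSpec:
    """A heart-rate band with edges in bpm."""

    low_bpm: float
    high_bpm: float

    def __post_init__(self):
        if not (0 < self.low_bpm < self.high_bpm):
            raise ValueError(f"need 0 < low < high bpm, got {self.low_bpm}, {self.high_bpm}")

    @property
    def low_hz(self) -> float:
        return self.low_bpm / 60.0

    @property
    def high_hz(self) -> float:
        return self.high_bpm / 60.0

    @property
    def center_bpm(self) -> float:
        return 0.5 * (self.low_bpm + self.high_bpm)

    @property
    def width_bpm(self) -> float:
        return self.high_bpm - self.low_bpm

    def contains(self, bpm: float) -> bool:
        return self.low_bpm <= bpm <= self.high_bpm


#: Wide band set: relaxed state up to tachycardia.
WIDE_BANDS = (BandSpec(60, 82), BandSpec(82, 105), BandSpec(105, 128), BandSpec(128, 150))
#: Narrow band set: emphasizes subtle changes around 80-96 bpm.
NARROW_BANDS = (BandSpec(60, 80), BandSpec(80, 88), BandSpec(88, 96), BandSpec(96, 150))


@dataclass(frozen=True)
class FilterBankConfig:
    """Band-pass filter bank: ordered bands, Butterworth order, gain.

    ``include_boundary`` adds one band below the first and one above the
    last (each one neighbor-width wide) so the decoder stays anchored at
    the edges of the HR range.
    """

    bands: tuple[BandSpec, ...] = WIDE_BANDS
    order: int = 2
    gain: float = 8.0
    include_boundary: bool = False

    def __post_init__(self):
        if len(self.bands) == 0:
            raise ValueError("filter bank needs at least one band")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        for a, b in zip(self.bands, self.bands[1:]):
            if b.low_bpm < a.high_bpm:
                raise ValueError("bands must be ordered, overlapping at most at shared edges")
        object.__setattr__(self, "bands", tuple(self.bands))

    @property
    def all_bands(self) -> tuple[BandSpec, ...]:
        """Bands including the two boundary bands when enabled."""
        if not self.include_boundary:
            return self.bands
        first, last = self.bands[0], self.bands[-1]
        below = BandSpec(max(first.low_bpm - first.width_bpm, 1.0), first.low_bpm)
        above = BandSpec(last.high_bpm, last.high_bpm + last.width_bpm)
        return (below, *self.bands, above)


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters.

    ``tau`` is the membrane time constant in seconds, ``v_thr`` the spiking
    threshold and ``v_reset`` the post-spike reset in normalized membrane
    units, ``refractory`` a hold time after a spike in seconds.

    ``unit_dc_gain`` selects the input normalization.  When False the
    membrane follows dv/dt = -v/tau + I(t) (steady state I*tau).  When True
    the injected current is scaled by 1/tau so that dv/dt = (I - v)/tau and
    a constant input drives the membrane toward I itself; this keeps the
    operating point (threshold 1, filter gain 8) independent of tau and is
    the normalization used by the processing pipeline.
    """

    tau: float = 0.024
    v_thr: float = 1.0
    v_reset: float = 0.0
    refractory: float = 0.0
    unit_dc_gain: bool = False

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.v_thr <= self.v_reset:
            raise ValueError("v_thr must exceed v_reset")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")


@dataclass
class SpikeTrain:
    """Strictly increasing event times in seconds with a source label."""

    times: np.ndarray
    label: str = ""
    duration: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def rate(self) -> float:
        """Mean rate over the train's duration (Hz)."""
        if self.duration:
            return len(self.times) / self.duration
        if len(self.times) < 2:
            return 0.0
        return len(self.times) / (self.times[-1] - self.times[0])


def make_filter_bank(cfg: FilterBankConfig, fs: float):
    """Design the causal Butterworth band-pass sections for each band."""
    nyq = fs / 2.0
    sections = []
    for band in cfg.all_bands:
        if band.high_hz >= nyq:
            raise ValueError(
                f"band edge {band.high_hz:.3f} Hz is at or above Nyquist ({nyq:.3f} Hz)")
        sos = sps.butter(cfg.order, [band.low_hz, band.high_hz],
                         btype="bandpass", fs=fs, output="sos")
        sections.append(sos)
    return sections


def apply_filter_bank(w: Waveform, cfg: FilterBankConfig) -> list[Waveform]:
    """Causal band-pass response of the input, one channel per band."""
    out = []
    for sos in make_filter_bank(cfg, w.fs):
        out.append(Waveform(sps.sosfilt(sos, w.samples), w.fs, w.t_start))
    return out


def rectify_amplify(channel: Waveform, gain: float) -> Waveform:
    """Full-wave rectification followed by amplification: gain * |x|."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return channel.with_samples(gain * np.abs(channel.samples))


def lif_encode(current: Waveform, p: LIFParams | None = None) -> SpikeTrain:
    """Integrate a current waveform through a LIF neuron and emit spikes.

    The membrane is stepped once per input sample with the exact exponential
    update for piecewise-constant current; a spike is emitted when the
    membrane reaches threshold, after which it resets and (optionally) holds
    for the refractory period.
    """
    if p is None:
        p = LIFParams()
    i = np.asarray(current.samples, dtype=float)
    dt = 1.0 / current.fs
    alpha = np.exp(-dt / p.tau)
    # drive toward I (unit DC gain) or I*tau (raw current injection)
    drive = i if p.unit_dc_gain else i * p.tau
    from ._engine import lif_step_series

    idx = lif_step_series(drive, alpha, p.v_thr, p.v_reset,
                          int(round(p.refractory * current.fs)))
    times = current.t_start + (idx + 1) / current.fs
    return SpikeTrain(times, label=current.__class__.__name__,
                      duration=current.duration)


def preprocess_pipeline(w: Waveform, cfg: FilterBankConfig | None = None,
                        p: LIFParams | None = None,
                        normalize: bool = True) -> list[SpikeTrain]:
    """filter -> rectify+amplify -> LIF encode, one spike train per band.

    ``normalize`` rescales the input waveform to unit RMS first, so that the
    studied operating point (gain 8, threshold 1) applies regardless of the
    raw amplitude scale of the source signal; the pipeline LIF uses the
    unit-DC-gain normalization (see :class:`LIFParams`).
    """
    if cfg is None:
        cfg = FilterBankConfig()
    if p is None:
        p = LIFParams(unit_dc_gain=True)
    x = w
    if normalize:
        rms = float(np.sqrt(np.mean(w.samples**2)))
        if rms > 0:
            x = w.with_samples(w.samples / rms)
    trains = []
    for band, ch in zip(cfg.all_bands, apply_filter_bank(x, cfg)):
        rect = rectify_amplify(ch, cfg.gain)
        st = lif_encode(rect, p)
        st.label = f"{band.low_bpm:g}-{band.high_bpm:g}bpm"
        trains.append(st)
    return trains
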