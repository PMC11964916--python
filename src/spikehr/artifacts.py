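"""Accelerometer-based motion-artifact removal for PPG.

Motion corrupts wrist PPG; a linear combination of the four band-filtered
PPG channels and twelve band-filtered accelerometer channels (four bands
per axis) is optimized so that the LIF firing rates of the combined
per-band signals match reference rates derived from a simultaneously
recorded ECG (a surrogate ground truth).  The optimization is
derivative-free (Nelder-Mead from seeded random initializations) because
the spike-rate objective has a flat, noisy gradient landscape.

The combination can be fitted globally, per subject, or per exercise type;
group-specific fits adapt to group-specific artifact structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as spo

from .preprocess import (FilterBankConfig, LIFParams, WIDE_BANDS,
                         apply_filter_bank, lif_encode, rectify_amplify)
from .signals import Waveform, signal_power

__all__ = [
    "ChannelMatrix",
    "CombinationWeights",
    "build_channels",
    "rate_series",
    "ecg_reference_rates",
    "combine_channels",
    "objective",
    "optimize_combination",
    "optimize_groups",
    "fit_rate_slope",
    "synthetic_motion_record",
]

#: artifact processing uses the four main HR bands (no boundary bands)
ARTIFACT_BANK = FilterBankConfig(bands=WIDE_BANDS, order=2, gain=8.0,
                                 include_boundary=False)
_PIPE_LIF = LIFParams(unit_dc_gain=True)
RATE_WINDOW = 2.0
RATE_STEP = 0.5


@dataclass
class ChannelMatrix:
    """Band-filtered PPG and accelerometer channels at a common rate.

    ``ppg``: (4, T) — PPG through the four HR bands.
    ``accel``: (12, T) — three axes x four bands, axis-major.
    """

    ppg: np.ndarray
    accel: np.ndarray
    fs: float

    def __post_init__(self):
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.ppg.shape[0] != 4 or self.accel.shape[0] != 12:
            raise ValueError("expected 4 PPG and 12 accelerometer channels")
        if self.ppg.shape[1] != self.accel.shape[1]:
            raise ValueError("channels must share length")


@dataclass
class CombinationWeights:
    """16 linear-combination coefficients: 4 PPG + 12 accelerometer."""

    ppg: np.ndarray
    accel: np.ndarray
    mode: str = "global"
    seed: int | None = None

    def __post_init__(self):
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.ppg.shape != (4,) or self.accel.shape != (12,):
            raise ValueError("expected 4 PPG and 12 accelerometer coefficients")
        if not (np.all(np.isfinite(self.ppg)) and np.all(np.isfinite(self.accel))):
            raise ValueError("coefficients must be finite")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.ppg, self.accel])

    @classmethod
    def from_vector(cls, v, **kw) -> "CombinationWeights":
        v = np.asarray(v, dtype=float)
        return cls(v[:4], v[4:16], **kw)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def build_channels(ppg: Waveform, accel_xyz, cfg: FilterBankConfig = ARTIFACT_BANK
                   ) -> ChannelMatrix:
    """Filter PPG and the three accelerometer axes into the four HR bands.

    Each source waveform is normalized to unit RMS first so the combination
    coefficients are comparable across modalities.
    """
    if len(accel_xyz) != 3:
        raise ValueError("expected three accelerometer axes")
    ppg_bands = [w.samples for w in
                 apply_filter_bank(ppg.with_samples(_unit_rms(ppg.samples)), cfg)]
    acc_bands = []
    for ax in accel_xyz:
        if ax.fs != ppg.fs or len(ax) != len(ppg):
            raise ValueError("accelerometer channels must be time-aligned with PPG")
        acc_bands.extend(w.samples for w in
                         apply_filter_bank(ax.with_samples(_unit_rms(ax.samples)), cfg))
    return ChannelMatrix(np.stack(ppg_bands), np.stack(acc_bands), ppg.fs)


def rate_series(train, duration: float, window: float = RATE_WINDOW,
                step: float = RATE_STEP) -> np.ndarray:
    """Sliding-window firing rate (Hz) of one spike train."""
    t = np.asarray(train.times if hasattr(train, "times") else train, dtype=float)
    starts = np.arange(0.0, duration - window + 1e-12, step)
    return (np.searchsorted(t, starts + window) - np.searchsorted(t, starts)) / window


def _band_rates(band_signals: np.ndarray, fs: float, gain: float) -> np.ndarray:
    dur = band_signals.shape[1] / fs
    out = []
    for x in band_signals:
        rect = rectify_amplify(Waveform(x, fs), gain)
        out.append(rate_series(lif_encode(rect, _PIPE_LIF), dur))
    return np.stack(out)


def ecg_reference_rates(ecg: Waveform, cfg: FilterBankConfig = ARTIFACT_BANK,
                        p: LIFParams = _PIPE_LIF) -> np.ndarray:
    """Per-band LIF firing-rate series of the ECG surrogate reference.

    The ECG is pushed through the same band-pass -> rectify -> LIF chain
    as the PPG; returns (4, n_windows) rates.
    """
    x = _unit_rms(ecg.samples)
    bands = np.stack([w.samples for w in apply_filter_bank(ecg.with_samples(x), cfg)])
    dur = len(ecg) / ecg.fs
    out = []
    for b in bands:
        rect = rectify_amplify(Waveform(b, ecg.fs), cfg.gain)
        out.append(rate_series(lif_encode(rect, p), dur))
    return np.stack(out)


def combine_channels(ch: ChannelMatrix, wts: CombinationWeights) -> np.ndarray:
    """Per-band combined signal, band-matched:

        combined_b = w_b * PPG_b + sum_axis w[axis, b] * accel[axis, b]

    Each of the 12 accelerometer coefficients corrects its own band, so a
    corruption that leaks into band b can be cancelled exactly by the
    matching band-filtered accelerometer channels without injecting
    out-of-band motion into the other bands' encoders.
    """
    acc = wts.accel.reshape(3, 4)
    corr = np.einsum("ab,abt->bt", acc, ch.accel.reshape(3, 4, -1))
    return wts.ppg[:, None] * ch.ppg + corr


def objective(wts: CombinationWeights, ch: ChannelMatrix, ref: np.ndarray,
              cfg: FilterBankConfig = ARTIFACT_BANK) -> float:
    """Mean per-band RRMSE between combined-signal LIF rates and reference.

    Each band's RMSE is normalized by the grand-mean reference rate (a
    near-silent reference band would otherwise blow up the ratio while
    carrying almost no information).
    """
    ref = np.asarray(ref, dtype=float)
    grand = np.mean(ref)
    if grand == 0:
        raise ValueError("reference rates are all zero; RRMSE undefined")
    rates = _band_rates(combine_channels(ch, wts), ch.fs, cfg.gain)
    n = min(rates.shape[1], ref.shape[1])
    vals = [np.sqrt(np.mean((rates[b, :n] - ref[b, :n]) ** 2)) / grand
            for b in range(4)]
    return float(np.mean(vals))


def raw_weights() -> CombinationWeights:
    """Identity combination: unit PPG coefficients, zero accelerometer."""
    return CombinationWeights(np.ones(4), np.zeros(12), mode="raw")


def optimize_combination(ch: ChannelMatrix, ref: np.ndarray,
                         cfg: FilterBankConfig = ARTIFACT_BANK,
                         n_iter: int = 20, n_restarts: int = 5,
                         seed: int = 0, mode: str = "global"
                         ) -> CombinationWeights:
    """Nelder-Mead fit of the 16 combination coefficients.

    Each restart draws accelerometer coefficients uniformly in [-1, 1]
    (PPG coefficients start at 1), runs ``n_iter`` simplex iterations, and
    the best vertex across restarts is returned.  Never returns weights
    worse than the best initialization.
    """
    rng = np.random.default_rng(seed)

    def f(v):
        try:
            return objective(CombinationWeights.from_vector(v), ch, ref, cfg)
        except ValueError:
            return np.inf

    best_v, best_f = None, np.inf
    step = np.concatenate([np.full(4, 0.1), np.full(12, 0.25)])
    for k in range(max(n_restarts, 1)):
        if k == 0:
            x0 = np.concatenate([np.ones(4), np.zeros(12)])  # raw-PPG start
        else:
            x0 = np.concatenate([np.ones(4), rng.uniform(-1, 1, 12)])
        f0 = f(x0)
        tries = 0
        while not np.isfinite(f0) and tries < 8:
            x0 = np.concatenate([np.ones(4), rng.uniform(-1, 1, 12)])
            f0 = f(x0)
            tries += 1
        if not np.isfinite(f0):
            raise RuntimeError("could not find a finite starting objective")
        if f0 < best_f:
            best_v, best_f = x0, f0
        if n_iter > 0:
            simplex = np.vstack([x0, x0 + np.diag(step)])
            res = spo.minimize(f, x0, method="Nelder-Mead",
                               options={"maxiter": n_iter, "xatol": 1e-9,
                                        "fatol": 1e-12,
                                        "initial_simplex": simplex})
            if res.fun < best_f:
                best_v, best_f = res.x, float(res.fun)
    return CombinationWeights.from_vector(best_v, mode=mode, seed=seed)


def optimize_groups(groups: dict, mode: str = "per_exercise", **kw) -> dict:
    """Fit one combination per group: {key: (ChannelMatrix, ref)} in,
    {key: CombinationWeights} out."""
    return {key: optimize_combination(ch, ref, mode=mode, **kw)
            for key, (ch, ref) in groups.items()}


def fit_rate_slope(reference, cleaned) -> float:
    """Least-squares slope of cleaned-signal rate vs reference rate.

    Unit slope indicates perfect agreement.  Raises on a constant
    reference (slope undefined).
    """
    x = np.asarray(reference, dtype=float).ravel()
    y = np.asarray(cleaned, dtype=float).ravel()
    if x.size < 2 or x.size != y.size:
        raise ValueError("need two series of equal length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined for a constant reference series")
    return float(np.polyfit(x, y, 1)[0])


def synthetic_motion_record(duration: float = 60.0, hr_bpm: float = 90.0,
                            coeff: float = 0.5, axis: int = 0,
                            fs: float = 125.0, seed: int = 0,
                            accel_band: tuple[float, float] = (1.4, 1.9)):
    """Synthetic motion-corruption fixture (no real wrist recordings).

    Builds a clean synthetic PPG (used both as the "ECG" surrogate
    reference and as the uncorrupted PPG), three synthetic accelerometer
    axes (band-limited Gaussian motion), and a corrupted PPG equal to the
    clean PPG plus ``coeff`` times the chosen accelerometer axis.

    Returns (corrupted_ppg, clean_ppg, [accel_x, accel_y, accel_z]).
    """
    from scipy import signal as sps
    from .signals import HRTrajectory, generate_ppg

    rng = np.random.default_rng(seed)
    traj = HRTrajectory.constant(hr_bpm)
    clean = generate_ppg(traj, fs=fs, duration=duration)
    clean = clean.with_samples(_unit_rms(clean.samples - clean.samples.mean()))
    n = len(clean)
    sos = sps.butter(2, accel_band, btype="bandpass", fs=fs, output="sos")
    accel = []
    for _ in range(3):
        a = sps.sosfilt(sos, rng.standard_normal(n))
        accel.append(Waveform(_unit_rms(a), fs))
    corrupted = clean.with_samples(clean.samples + coeff * accel[axis].samples)
    return corrupted, clean, accel
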