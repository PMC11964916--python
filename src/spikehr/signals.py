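"""Synthetic PPG generation with controlled heart-rate dynamics and noise.

A single PPG pulse is modelled as the sum of two Gaussians laid out on a
circular phase variable: a point rotates at angular velocity
``omega = 2*pi*HR/60`` and the waveform value is read off a fixed pulse
profile expressed in the polar angle ``theta``.  Distributing pulses through
circular motion makes arbitrary heart-rate trajectories easy to honour: the
phase advances as the integral of ``omega(t)``, so steps or ramps in HR never
produce phase discontinuities.

Calibrated additive noise (white or colored, at a prescribed SNR in dB) is
produced by spectrally shaping Gaussian white noise in the frequency domain
and renormalizing to the exact target power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal as sps

__all__ = [
    "Waveform",
    "PPGPulseSpec",
    "HRTrajectory",
    "NoiseSpec",
    "NOISE_COLORS",
    "PulseFitError",
    "generate_ppg",
    "signal_power",
    "colored_noise",
    "add_noise",
    "fit_pulse_params",
]

#: Spectral exponent alpha for each supported noise color: the shaped
#: power spectral density is proportional to f**alpha.
NOISE_COLORS = {"white": 0.0, "pink": -1.0, "brown": -2.0, "blue": 1.0, "violet": 2.0}


class PulseFitError(RuntimeError):
    """Raised when a pulse cannot be isolated or fitted from a waveform."""


@dataclass
class Waveform:
    """Uniformly sampled real-valued time series.

    Parameters
    ----------
    samples : array-like of float
    fs : float
        Sampling rate in Hz (> 0).
    t_start : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t_start: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("waveform samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(len(self.samples)) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        return Waveform(samples, self.fs, self.t_start)


@dataclass(frozen=True)
class PPGPulseSpec:
    """Two-Gaussian pulse shape on the circular phase.

    ``a1, a2`` are the peak amplitudes, ``b1, b2`` the Gaussian width
    parameters (radians, used directly as the Gaussian sigma), ``theta1,
    theta2`` the Gaussian centers in (-pi, pi], and ``t0`` a phase-offset
    time in seconds.  ``width_is_two_sigma`` switches to the alternative
    reading in which the sigma equals ``2*b_i``.
    """

    a1: float = 0.19
    a2: float = 0.07
    b1: float = 0.42
    b2: float = 0.5
    theta1: float = -0.7
    theta2: float = 0.4
    t0: float = 0.403
    width_is_two_sigma: bool = False

    def __post_init__(self):
        if self.b1 <= 0 or self.b2 <= 0:
            raise ValueError("Gaussian widths b1, b2 must be positive")
        for name in ("theta1", "theta2"):
            th = getattr(self, name)
            if not (-np.pi < th <= np.pi):
                raise ValueError(f"{name} must lie in (-pi, pi], got {th}")

    @property
    def sigmas(self) -> tuple[float, float]:
        k = 2.0 if self.width_is_two_sigma else 1.0
        return (k * self.b1, k * self.b2)

    def profile(self, theta: np.ndarray) -> np.ndarray:
        """Pulse amplitude as a function of the polar angle theta."""
        theta = np.asarray(theta, dtype=float)
        out = np.zeros_like(theta)
        for a, sig, th_c in zip((self.a1, self.a2), self.sigmas, (self.theta1, self.theta2)):
            # circular distance so that pulses wrap seamlessly at +-pi
            d = np.arctan2(np.sin(theta - th_c), np.cos(theta - th_c))
            out += a * np.exp(-(d**2) / (2.0 * sig**2))
        return out


class HRTrajectory:
    """Piecewise heart-rate trajectory HR(t) in bpm.

    Holds breakpoints and values with either step ('previous') or linear
    interpolation, and a declared admissible HR range.
    """

    def __init__(self, times, values, kind: str = "previous",
                 hr_range: tuple[float, float] = (60.0, 150.0)):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) == 0:
            raise ValueError("trajectory needs at least one breakpoint")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("trajectory times must be non-decreasing")
        if kind not in ("previous", "linear"):
            raise ValueError(f"unknown interpolation kind {kind!r}")
        self.kind = kind
        self.hr_range = (float(hr_range[0]), float(hr_range[1]))
        lo, hi = self.hr_range
        if np.any(self.values < lo) or np.any(self.values > hi):
            raise ValueError(
                f"HR values must lie within the declared range [{lo}, {hi}] bpm")

    @classmethod
    def constant(cls, bpm: float, **kw) -> "HRTrajectory":
        return cls([0.0], [bpm], **kw)

    @classmethod
    def staircase(cls, levels, step_duration: float, **kw) -> "HRTrajectory":
        """Hold each HR level in ``levels`` for ``step_duration`` seconds."""
        levels = np.asarray(levels, dtype=float)
        t = np.arange(len(levels)) * float(step_duration)
        return cls(t, levels, kind="previous", **kw)

    @classmethod
    def ramp(cls, bpm_start: float, bpm_end: float, duration: float, **kw) -> "HRTrajectory":
        return cls([0.0, float(duration)], [bpm_start, bpm_end], kind="linear", **kw)

    def hr_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "linear":
            return np.interp(t, self.times, self.values)
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, len(self.times) - 1)
        return self.values[idx]

    def omega_at(self, t) -> np.ndarray:
        """Angular velocity omega = 2*pi*HR/60 in rad/s."""
        return 2.0 * np.pi * self.hr_at(t) / 60.0

    def covers(self, duration: float) -> bool:
        return self.times[0] <= 0.0 or len(self.times) == 1


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-noise prescription: SNR in dB, spectral color, RNG seed."""

    snr_db: float
    color: str = "white"
    seed: int = 0

    def __post_init__(self):
        if self.color not in NOISE_COLORS:
            raise ValueError(
                f"unknown noise color {self.color!r}; choose from {sorted(NOISE_COLORS)}")


def generate_ppg(traj: HRTrajectory, pulse: PPGPulseSpec | None = None,
                 fs: float = 125.0, duration: float = 10.0) -> Waveform:
    """Generate a synthetic PPG waveform for a heart-rate trajectory.

    The phase advances as ``phi(t) = integral of omega`` so that time-varying
    HR is honoured without phase jumps; the polar angle is
    ``theta(t) = atan2(sin(psi), cos(psi))`` with ``psi = phi(t) - phi(t0) - pi``
    and the output is the two-Gaussian pulse profile evaluated at ``theta``.
    For constant HR the output is periodic with period ``60/HR``.
    """
    if pulse is None:
        pulse = PPGPulseSpec()
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if fs < 50:
        raise ValueError(f"fs must be at least 50 Hz to resolve pulse morphology, got {fs}")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    omega = traj.omega_at(t)
    # accumulated phase; trapezoidal integral of omega from 0 to t
    phi = np.concatenate(([0.0], np.cumsum(0.5 * (omega[1:] + omega[:-1])) / fs))
    # phase at t0 (t0 may exceed the grid for very short signals)
    omega0 = float(traj.omega_at(pulse.t0))
    if pulse.t0 <= t[-1] and n > 1:
        phi_t0 = float(np.interp(pulse.t0, t, phi))
    else:
        phi_t0 = omega0 * pulse.t0
    psi = phi - phi_t0 - np.pi
    theta = np.arctan2(np.sin(psi), np.cos(psi))
    return Waveform(pulse.profile(theta), fs)


def signal_power(w: Waveform) -> float:
    """Mean of squared samples."""
    if len(w) == 0:
        raise ValueError("cannot compute power of an empty waveform")
    return float(np.mean(w.samples**2))


def colored_noise(n: int, color: str = "white", seed: int | np.random.Generator = 0) -> np.ndarray:
    """Unit-power zero-mean noise with power spectral density ~ f**alpha.

    White Gaussian noise is shaped in the frequency domain by scaling the
    spectral amplitudes by ``f**(alpha/2)`` (DC bin zeroed), then the result
    is recentred and renormalized to exactly unit average power.
    """
    if n < 2:
        raise ValueError("need at least two samples of noise")
    alpha = NOISE_COLORS[color]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)  # cycles/sample; absolute rate is irrelevant to the shape
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (alpha / 2.0)
    spec *= shape
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise RuntimeError("degenerate noise draw")
    return x / rms


def add_noise(w: Waveform, spec: NoiseSpec) -> Waveform:
    """Add calibrated noise: P_noise = P_signal * 10**(-SNR/10), exactly."""
    p_sig = signal_power(w)
    if p_sig <= 0:
        raise ValueError("signal power is zero; SNR is undefined")
    p_noise = p_sig * 10.0 ** (-spec.snr_db / 10.0)
    noise = colored_noise(len(w), spec.color, spec.seed) * np.sqrt(p_noise)
    return w.with_samples(w.samples + noise)


def _pulse_model(t, a1, a2, b1, b2, th1, th2, t0, omega):
    psi = omega * (t - t0) - np.pi
    theta = np.arctan2(np.sin(psi), np.cos(psi))
    out = np.zeros_like(t)
    for a, b, thc in ((a1, b1, th1), (a2, b2, th2)):
        d = np.arctan2(np.sin(theta - thc), np.cos(theta - thc))
        out += a * np.exp(-(d**2) / (2.0 * b**2))
    return out


def extract_pulse(w: Waveform, min_spacing: float | None = None) -> Waveform:
    """Isolate one pulse: the samples between the midpoints of two
    consecutive valleys of the waveform.

    ``min_spacing`` (s) enforces a minimum separation between detected
    valleys (e.g. half a beat period) so noise wiggles in the flat
    inter-pulse trough are not mistaken for pulse boundaries.
    """
    z = w.samples
    if len(z) < 8 or np.ptp(z) <= 0:
        raise PulseFitError("waveform is flat or too short to contain a pulse")
    prom = 0.1 * np.ptp(z)
    dist = max(int((min_spacing or 0) * w.fs), 1)
    valleys, _ = sps.find_peaks(-z, prominence=prom, distance=dist)
    if len(valleys) < 3:
        # pad with the boundaries, which act as half-valleys for short records
        valleys = np.unique(np.concatenate(([0], valleys, [len(z) - 1])))
    if len(valleys) < 3:
        raise PulseFitError("no detectable valleys bounding a pulse")
    mids = ((valleys[:-1] + valleys[1:]) // 2)
    i0, i1 = int(mids[0]), int(mids[1])
    if i1 - i0 < 4:
        raise PulseFitError("detected pulse is degenerate")
    return Waveform(z[i0:i1 + 1], w.fs, w.t_start + i0 / w.fs)


def fit_pulse_params(pulse_wave: Waveform, traj: HRTrajectory) -> PPGPulseSpec:
    """Least-squares fit of the two-Gaussian pulse model to one pulse.

    The pulse is isolated as the data between the midpoints of two
    consecutive valleys; the angular velocity is taken from the trajectory
    (assumed locally constant over one beat).  The phase-offset time ``t0``
    is gauge-degenerate with the Gaussian centers, so it is pinned first
    from the central valley position (the polar angle crosses +-pi, i.e. the
    inter-pulse trough, at ``t = t0`` modulo one beat period), and the six
    shape parameters are then fitted.  Raises :class:`PulseFitError` on flat
    input or when no valleys can be detected.
    """
    omega0 = float(np.mean(traj.omega_at(pulse_wave.times)))
    seg = extract_pulse(pulse_wave, min_spacing=0.6 * 2 * np.pi / omega0)
    t = seg.times
    z = seg.samples
    omega = float(np.mean(traj.omega_at(t)))
    period = 2 * np.pi / omega

    # pin t0 from the central trough of the segment
    interior = slice(1, len(z) - 1)
    i_min = 1 + int(np.argmin(z[interior]))
    t0 = float(t[i_min] % period)

    # data-driven initialization (deliberately independent of any defaults)
    a0 = float(np.max(z))
    if a0 <= 0:
        raise PulseFitError("pulse has no positive excursion")
    p0 = [a0, a0 / 3.0, 0.4, 0.5, -0.5, 0.5]
    lo = [0.0, 0.0, 0.05, 0.05, -np.pi, -np.pi]
    hi = [3 * a0, 3 * a0, np.pi, np.pi, np.pi, np.pi]

    def resid(p):
        return _pulse_model(t, *p, t0, omega) - z

    try:
        res = optimize.least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
    except ValueError as e:  # pragma: no cover - defensive
        raise PulseFitError(f"least-squares fit failed: {e}") from e
    if not res.success:
        raise PulseFitError("least-squares fit did not converge")
    a1, a2, b1, b2, th1, th2 = res.x
    # order the two Gaussians so the larger-amplitude one comes first
    if a2 > a1:
        a1, a2, b1, b2, th1, th2 = a2, a1, b2, b1, th2, th1
    th1 = float(np.arctan2(np.sin(th1), np.cos(th1)))
    th2 = float(np.arctan2(np.sin(th2), np.cos(th2)))
    if th1 == -np.pi:
        th1 = np.pi
    if th2 == -np.pi:
        th2 = np.pi
    return PPGPulseSpec(float(a1), float(a2), float(b1), float(b2), th1, th2, t0)
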