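"""End-to-end evaluation helpers: noise-robustness trials for state decoding."""

from __future__ import annotations

import numpy as np

from .architectures import (DecoderConfig, MONONSM_PARAMS, NNNSM_PARAMS,
                            WTA_PARAMS, build_state_machine,
                            drive_state_machine, read_state, run_decoder)
from .preprocess import (FilterBankConfig, SpikeTrain, WIDE_BANDS,
                         preprocess_pipeline)
from .signals import HRTrajectory, NoiseSpec, add_noise, generate_ppg

__all__ = ["state_noise_trial", "decoder_band_trains", "BAND_CENTER_STAIRCASE"]

#: staircase visiting each HR band's center, the standard state-task input
BAND_CENTER_STAIRCASE = tuple(b.center_bpm for b in WIDE_BANDS)

_PARAMS = {"wta": WTA_PARAMS, "nnnsm": NNNSM_PARAMS, "mononsm": MONONSM_PARAMS}


def decoder_band_trains(wave, seed: int = 0,
                        cfg: DecoderConfig | None = None) -> list[SpikeTrain]:
    """Per-band spike trains taken from the decoder layer.

    The state machines receive the spikes of the 13-neuron decoder layer
    rather than the raw band encoders: decoder neurons whose bpm centers
    fall inside a band are merged into that band's input train.  The
    Gaussian pooling of the decoder suppresses harmonic leakage of the
    pulse waveform into distant bands, which the raw encoders pass through.
    """
    if cfg is None:
        cfg = DecoderConfig()
    trains = preprocess_pipeline(wave, cfg.filter_bank)
    raster = run_decoder(trains, cfg, duration=wave.duration, seed=seed)
    lo, _ = raster.pop_slices["dec"]
    centers = cfg.centers
    out = []
    for band in cfg.filter_bank.bands:
        members = [k for k, c in enumerate(centers)
                   if band.low_bpm <= c < band.high_bpm
                   or (c == band.high_bpm == cfg.hr_range[1])]
        mask = np.isin(raster.ids - lo, members)
        t = np.unique(raster.times[mask])
        out.append(SpikeTrain(t, label=f"dec:{band.low_bpm:g}-{band.high_bpm:g}",
                              duration=wave.duration))
    return out


def state_noise_trial(snr_db: float | None, color: str | None, seed: int,
                      duration: float = 100.0, arch: str = "wta",
                      fs: float = 125.0, window: float = 0.5,
                      settle: float = 5.0) -> float:
    """RRMSE of state decoding on one noisy synthetic trial.

    A staircase through the four band centers is synthesized, optionally
    corrupted at ``snr_db`` with the given noise color, pushed through the
    preprocessing chain and the chosen state machine, and the decoded
    band-center HR is compared to the true HR (windows during the first
    ``settle`` seconds of each step are excluded; undecided windows count
    with the previous decided state).
    """
    levels = np.array(BAND_CENTER_STAIRCASE)
    dwell = duration / len(levels)
    traj = HRTrajectory.staircase(levels, dwell)
    wave = generate_ppg(traj, fs=fs, duration=duration)
    if snr_db is not None:
        wave = add_noise(wave, NoiseSpec(snr_db, color or "white", seed))
    trains = decoder_band_trains(wave, seed=seed)
    spec = build_state_machine(_PARAMS[arch], seed=seed)
    raster = drive_state_machine(spec, trains, duration=duration, seed=seed)
    trace = read_state(raster, window=window)

    centers = np.array([b.center_bpm for b in WIDE_BANDS])
    # carry the last decided state through undecided windows
    state = trace.state_index.copy()
    last = -1
    for i, s in enumerate(state):
        if s < 0:
            state[i] = last
        else:
            last = s
    valid = state >= 0
    # exclude the settling period after each step change
    step_start = np.floor(trace.times / dwell) * dwell
    valid &= (trace.times - step_start) >= settle
    if not np.any(valid):
        return float("nan")
    pred = centers[state[valid]]
    target = traj.hr_at(trace.times[valid])
    return float(np.sqrt(np.mean((pred - target) ** 2)) / np.mean(target))
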