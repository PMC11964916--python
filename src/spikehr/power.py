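"""Evaluation metrics and the neuromorphic-chip power/energy model.

Power is modelled from per-operation energy costs of the emulated
mixed-signal processor at 1.8 V: generating a spike, encoding it and
appending destinations, broadcasting within a core, routing to another
core, and extending the output pulse.  Total power is the rate-weighted sum
over neurons:

    P = sum_n r_n * (E_spike + E_enc + N_cores*(E_br + E_rt)
                     + N_cam_match * E_pulse)

where ``r_n`` is neuron n's firing rate, ``N_cores`` the number of
destination cores its spikes are sent to and ``N_cam_match`` the number of
postsynaptic neurons receiving them.

The accuracy metric is the relative root-mean-square error: RMSE divided
by the mean of the observed (ground-truth) values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnergyTable",
    "PowerTopology",
    "rrmse",
    "estimate_power",
    "energy",
    "battery_energy",
    "power_of_raster",
    "calibrate_fanout",
    "noise_sweep",
]


@dataclass(frozen=True)
class EnergyTable:
    """Per-operation energy costs in joules (defaults at 1.8 V)."""

    e_spike: float = 883e-12   # generate one spike
    e_enc: float = 883e-12     # encode one spike and append destinations
    e_br: float = 6.84e-9      # broadcast events to the same core
    e_rt: float = 360e-12      # route events to a different core
    e_pulse: float = 324e-12   # extend generated pulse

    def __post_init__(self):
        for name in ("e_spike", "e_enc", "e_br", "e_rt", "e_pulse"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PowerTopology:
    """Per-neuron firing rates and routing fan-out.

    ``rates`` in Hz; ``n_cores`` (destination core count) and
    ``n_cam_match`` (postsynaptic neuron count) may be scalars applied to
    every neuron or per-neuron arrays.
    """

    rates: np.ndarray
    n_cores: np.ndarray | int = 1
    n_cam_match: np.ndarray | int = 0

    def __post_init__(self):
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be non-negative")
        for name in ("n_cores", "n_cam_match"):
            v = np.broadcast_to(np.asarray(getattr(self, name)), self.rates.shape)
            if np.any(v < 0) or not np.issubdtype(v.dtype, np.integer) and np.any(v % 1):
                raise ValueError(f"{name} must be non-negative integers")
            setattr(self, name, v.astype(int))


def rrmse(predicted, actual) -> float:
    """Root-mean-square error divided by the mean of the observed values.

    0 indicates perfect agreement; scale-invariant under joint positive
    rescaling of both series.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.size == 0:
        raise ValueError("series must have equal nonzero length")
    mean_obs = np.mean(actual)
    if mean_obs == 0:
        raise ValueError("RRMSE undefined: mean of observed values is zero")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)) / mean_obs)


def estimate_power(topo: PowerTopology, e: EnergyTable | None = None) -> float:
    """Total chip power in watts for the given rates and routing fan-out."""
    if e is None:
        e = EnergyTable()
    per_spike = (e.e_spike + e.e_enc + topo.n_cores * (e.e_br + e.e_rt)
                 + topo.n_cam_match * e.e_pulse)
    return float(np.sum(topo.rates * per_spike))


def energy(power: float, duration: float) -> float:
    """Energy in joules: power (W) x duration (s)."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    return power * duration


def battery_energy(voltage: float, capacity_mah: float) -> float:
    """Stored energy (J) of a battery: V x mAh x 3.6 J/(V*mAh)."""
    if voltage <= 0 or capacity_mah <= 0:
        raise ValueError("voltage and capacity must be positive")
    return voltage * capacity_mah * 3.6


def power_of_raster(raster, e: EnergyTable | None = None,
                    n_cores: int = 1, n_cam_match=None) -> float:
    """Estimate power for a simulated raster.

    ``n_cam_match=None`` uses the realized fan-out of the network when the
    raster carries one (attribute ``fan_out``), else 0.
    """
    rates = raster.per_neuron_rates()
    if n_cam_match is None:
        n_cam_match = getattr(raster, "fan_out", None)
        if n_cam_match is None:
            n_cam_match = 0
    return estimate_power(PowerTopology(rates, n_cores, n_cam_match), e)


def calibrate_fanout(mean_rate: float, n_neurons: int, target_power: float,
                     n_cores: int = 1, e: EnergyTable | None = None) -> float:
    """Fan-out (N_cam_match) that reconciles a mean rate with a printed power.

    Returns the per-neuron postsynaptic count at which ``n_neurons`` neurons
    firing at ``mean_rate`` dissipate ``target_power``.
    """
    if e is None:
        e = EnergyTable()
    base = mean_rate * n_neurons * (e.e_spike + e.e_enc + n_cores * (e.e_br + e.e_rt))
    per_match = mean_rate * n_neurons * e.e_pulse
    return (target_power - base) / per_match


def noise_sweep(run_trial, snr_grid, colors=("white",), n_seeds: int = 10,
                clean_label: str = "clean") -> pd.DataFrame:
    """Mean +- sd RRMSE over noise conditions.

    ``run_trial(snr_db, color, seed)`` must return an RRMSE value; SNR None
    denotes the clean condition.  Returns a tidy DataFrame with columns
    (snr_db, color, mean, sd, n); sd is NaN for a single seed.
    """
    rows = []
    conditions = [(None, clean_label)] + [(s, c) for c in colors for s in snr_grid]
    for snr, color in conditions:
        vals = np.array([run_trial(snr, color if snr is not None else None, seed)
                         for seed in range(n_seeds)], dtype=float)
        rows.append({
            "snr_db": np.nan if snr is None else float(snr),
            "color": color,
            "mean": vals.mean(),
            "sd": vals.std(ddof=1) if n_seeds > 1 else np.nan,
            "n": n_seeds,
        })
    return pd.DataFrame(rows)
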