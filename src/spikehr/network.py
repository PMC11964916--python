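"""Clock-driven simulator for recurrent LIF populations.

Networks are declared as populations (excitatory or inhibitory) plus
probabilistic connections; :func:`realize_connectivity` draws an explicit
adjacency (each pre/post pair wired independently with the stated
probability), and :func:`simulate` integrates the resulting network with
exponentially decaying synaptic currents.

Conventions
-----------
* Synaptic efficacies are expressed in membrane (threshold) units of
  steady-state drive: a presynaptic population firing at rate ``r`` through
  weight ``w`` and synaptic time constant ``tau_s`` contributes a mean drive
  of ``w * r * tau_s`` toward the membrane, whose threshold is 1 by default.
* Device mismatch (the heterogeneity of analog neuron arrays) is emulated as
  seeded multiplicative Gaussian jitter on membrane time constants,
  thresholds, and synaptic weights, with a configurable coefficient of
  variation.
* Everything is deterministic given the network seed: connectivity draws,
  mismatch draws, and Poisson input realizations use independent child
  streams of one seed sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import LIFParams, SpikeTrain

__all__ = [
    "PopulationSpec",
    "ConnectionSpec",
    "NetworkSpec",
    "PoissonInput",
    "SpikeTrainInput",
    "SpikeRaster",
    "RunawayExcitationError",
    "WTATieError",
    "DEFAULT_NEURON",
    "SLOW_TAU",
    "FAST_TAU",
    "realize_connectivity",
    "simulate",
    "population_rate",
    "wta_rate_oracle",
]

#: Default neuron for recurrent populations: 20 ms membrane, threshold 1,
#: 3 ms refractory period to bound attractor firing rates.
DEFAULT_NEURON = LIFParams(tau=0.02, v_thr=1.0, v_reset=0.0, refractory=0.003)

#: Slow synapses (recurrent excitation; gives the attractors their
#: hundreds-of-milliseconds integration time scale) and fast synapses
#: (inhibition and feed-forward input), in seconds.
SLOW_TAU = 0.1
FAST_TAU = 0.01


class RunawayExcitationError(RuntimeError):
    """The network exceeded its per-neuron firing-rate cap: the parameters
    are outside the balanced regime."""


class WTATieError(ValueError):
    """The winner-take-all rate equations have no unique winner because the
    maximal inputs are tied."""


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    role: str = "excitatory"
    lif: LIFParams = DEFAULT_NEURON

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("population size must be >= 1")
        if self.role not in ("excitatory", "inhibitory"):
            raise ValueError(f"role must be excitatory|inhibitory, got {self.role!r}")


@dataclass(frozen=True)
class ConnectionSpec:
    """Probabilistic projection between two declared populations.

    ``weight`` must be positive for excitatory sources and negative for
    inhibitory sources.  Within-population projections never wire a neuron
    to itself.
    """

    source: str
    target: str
    probability: float
    weight: float
    synapse_tau: float = FAST_TAU

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("connection probability must be in [0, 1]")
        if self.synapse_tau <= 0:
            raise ValueError("synapse_tau must be positive")
        if self.weight == 0:
            raise ValueError("connection weight must be nonzero")


@dataclass(frozen=True)
class PoissonInput:
    """External drive from ``n_sources`` independent Poisson units."""

    rate: float
    weight: float
    probability: float = 0.3
    n_sources: int = 16
    synapse_tau: float = FAST_TAU

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("Poisson rate must be non-negative")


@dataclass(frozen=True)
class SpikeTrainInput:
    """External drive from one spike train (e.g. a band LIF encoder).

    ``weight`` may be a scalar (edges drawn with ``probability``) or a
    per-target vector of length equal to the target population size, in
    which case the projection is dense and deterministic (used for the
    Gaussian-weighted decoder fan-in).
    """

    times: np.ndarray
    weight: float | np.ndarray = 1.0
    probability: float = 1.0
    synapse_tau: float = FAST_TAU

    def __post_init__(self):
        t = self.times.times if isinstance(self.times, SpikeTrain) else self.times
        object.__setattr__(self, "times", np.asarray(t, dtype=float))


@dataclass
class NetworkSpec:
    populations: list[PopulationSpec]
    connections: list[ConnectionSpec]
    mismatch_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        self._by_name = {p.name: p for p in self.populations}
        for c in self.connections:
            for endpoint in (c.source, c.target):
                if endpoint not in self._by_name:
                    raise ValueError(f"connection references unknown population {endpoint!r}")
            role = self._by_name[c.source].role
            if role == "excitatory" and c.weight < 0:
                raise ValueError(f"excitatory source {c.source!r} must have positive weight")
            if role == "inhibitory" and c.weight > 0:
                raise ValueError(f"inhibitory source {c.source!r} must have negative weight")

    def population(self, name: str) -> PopulationSpec:
        return self._by_name[name]

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations)

    def offsets(self) -> dict[str, tuple[int, int]]:
        out, lo = {}, 0
        for p in self.populations:
            out[p.name] = (lo, lo + p.size)
            lo += p.size
        return out


@dataclass
class RealizedNetwork:
    """Explicit adjacency drawn from a :class:`NetworkSpec`."""

    spec: NetworkSpec
    pop_slices: dict[str, tuple[int, int]]
    edges: list[np.ndarray]          # per connection: (n_edges, 2) [pre, post] global ids
    edge_weights: list[np.ndarray]   # per connection, mismatch applied
    tau_m: np.ndarray
    v_thr: np.ndarray
    v_reset: np.ndarray
    refractory: np.ndarray

    def edge_count(self, i: int) -> int:
        return len(self.edges[i])

    def fan_out(self) -> np.ndarray:
        """Number of postsynaptic targets per neuron (for the power model)."""
        n = self.spec.n_neurons
        out = np.zeros(n, dtype=int)
        for e in self.edges:
            if len(e):
                out += np.bincount(e[:, 0], minlength=n)
        return out


def _jitter(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv <= 0:
        return values
    factor = np.clip(1.0 + cv * rng.standard_normal(values.shape), 0.05, None)
    return values * factor


def realize_connectivity(spec: NetworkSpec, seed: int | None = None) -> RealizedNetwork:
    """Draw the explicit adjacency and per-neuron parameters for a network.

    Each (pre, post) pair is wired independently with the connection's
    probability, so realized in-degrees are binomial.  Mismatch jitter is
    applied here to membrane time constants, thresholds and edge weights.
    """
    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    rng_conn, rng_mis = [np.random.default_rng(s) for s in ss.spawn(2)]
    slices = spec.offsets()
    n = spec.n_neurons

    tau_m = np.empty(n)
    v_thr = np.empty(n)
    v_reset = np.empty(n)
    refractory = np.empty(n)
    for p in spec.populations:
        lo, hi = slices[p.name]
        tau_m[lo:hi] = p.lif.tau
        v_thr[lo:hi] = p.lif.v_thr
        v_reset[lo:hi] = p.lif.v_reset
        refractory[lo:hi] = p.lif.refractory
    tau_m = _jitter(rng_mis, tau_m, spec.mismatch_cv)
    v_thr = _jitter(rng_mis, v_thr, spec.mismatch_cv)

    edges, weights = [], []
    for c in spec.connections:
        slo, shi = slices[c.source]
        tlo, thi = slices[c.target]
        ns, nt = shi - slo, thi - tlo
        if c.probability >= 1.0:
            mask = np.ones((ns, nt), dtype=bool)
        elif c.probability <= 0.0:
            mask = np.zeros((ns, nt), dtype=bool)
        else:
            mask = rng_conn.random((ns, nt)) < c.probability
        if c.source == c.target:
            np.fill_diagonal(mask, False)
        pre, post = np.nonzero(mask)
        e = np.column_stack([pre + slo, post + tlo]).astype(np.int64)
        w = np.full(len(e), c.weight)
        w = np.sign(w) * np.abs(_jitter(rng_mis, np.abs(w), spec.mismatch_cv))
        edges.append(e)
        weights.append(w)
    return RealizedNetwork(spec, slices, edges, weights, tau_m, v_thr, v_reset, refractory)


@dataclass
class SpikeRaster:
    """Spike events: parallel arrays of times (s) and global neuron ids."""

    times: np.ndarray
    ids: np.ndarray
    pop_slices: dict[str, tuple[int, int]]
    duration: float
    mean_drive_exc: np.ndarray | None = None
    mean_drive_inh: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.times)

    def population_events(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.pop_slices[name]
        m = (self.ids >= lo) & (self.ids < hi)
        return self.times[m], self.ids[m]

    def mean_rates(self) -> dict[str, float]:
        """Per-population mean rate in Hz per neuron over the full duration."""
        out = {}
        for name, (lo, hi) in self.pop_slices.items():
            m = (self.ids >= lo) & (self.ids < hi)
            out[name] = float(np.count_nonzero(m)) / ((hi - lo) * self.duration)
        return out

    def per_neuron_rates(self) -> np.ndarray:
        n = max(hi for _, hi in self.pop_slices.values()) if self.pop_slices else 0
        return np.bincount(self.ids, minlength=n) / self.duration


def _input_events_and_edges(inputs, pop_slices, spec, n_neurons, duration, dt, rng):
    """Realize external inputs as virtual source units: returns (events, edges)."""
    ev_steps, ev_units = [], []
    edges = []  # (unit, target, weight, tau)
    unit = n_neurons
    nsteps = int(round(duration / dt))
    for pop_name, specs in inputs.items():
        if pop_name not in pop_slices:
            raise ValueError(f"external input references unknown population {pop_name!r}")
        lo, hi = pop_slices[pop_name]
        size = hi - lo
        if not isinstance(specs, (list, tuple)):
            specs = [specs]
        for inp in specs:
            if isinstance(inp, PoissonInput):
                for _ in range(inp.n_sources):
                    if inp.rate > 0:
                        n_exp = int(inp.rate * duration + 6 * np.sqrt(inp.rate * duration) + 16)
                        t = np.cumsum(rng.exponential(1.0 / inp.rate, size=n_exp))
                        t = t[t < duration]
                    else:
                        t = np.empty(0)
                    steps = np.floor(t / dt).astype(np.int64)
                    ev_steps.append(np.clip(steps, 0, nsteps - 1))
                    ev_units.append(np.full(len(steps), unit, dtype=np.int64))
                    wired = np.nonzero(rng.random(size) < inp.probability)[0]
                    for j in wired:
                        edges.append((unit, lo + j, float(inp.weight), inp.synapse_tau))
                    unit += 1
            elif isinstance(inp, SpikeTrainInput):
                t = inp.times[(inp.times >= 0) & (inp.times < duration)]
                steps = np.floor(t / dt).astype(np.int64)
                ev_steps.append(np.clip(steps, 0, nsteps - 1))
                ev_units.append(np.full(len(steps), unit, dtype=np.int64))
                w = inp.weight
                if np.ndim(w) == 0:
                    wired = np.nonzero(rng.random(size) < inp.probability)[0]
                    for j in wired:
                        edges.append((unit, lo + j, float(w), inp.synapse_tau))
                else:
                    w = np.asarray(w, dtype=float)
                    if len(w) != size:
                        raise ValueError(
                            f"weight vector length {len(w)} != population size {size}")
                    for j in range(size):
                        if w[j] != 0.0:
                            edges.append((unit, lo + j, float(w[j]), inp.synapse_tau))
                unit += 1
            else:
                raise TypeError(f"unsupported external input type {type(inp).__name__}")
    if ev_steps:
        steps = np.concatenate(ev_steps)
        units = np.concatenate(ev_units)
        order = np.argsort(steps, kind="stable")
        steps, units = steps[order], units[order]
    else:
        steps = np.empty(0, dtype=np.int64)
        units = np.empty(0, dtype=np.int64)
    return steps, units, edges, unit


def simulate(spec: NetworkSpec, external_inputs=None, duration: float = 1.0,
             dt: float = 1e-4, seed: int | None = None,
             rate_cap: float = 1000.0) -> SpikeRaster:
    """Simulate a network and return all emitted events.

    ``external_inputs`` maps population name to an input spec (or list of
    them): :class:`PoissonInput` or :class:`SpikeTrainInput`.  Deterministic
    given the seed (defaults to the spec's seed).  Raises
    :class:`RunawayExcitationError` when any neuron's average rate budget
    (``rate_cap`` Hz per neuron over the run) is exhausted, which signals
    parameters outside the balanced regime.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (0 < dt <= 1e-3):
        raise ValueError("dt must be positive and at most 1 ms")
    base = spec.seed if seed is None else seed
    net = realize_connectivity(spec, seed=base)
    rng_inp = np.random.default_rng(np.random.SeedSequence(base).spawn(3)[2])
    n = spec.n_neurons
    nsteps = int(round(duration / dt))

    ext_steps, ext_units, in_edges, n_units = _input_events_and_edges(
        external_inputs or {}, net.pop_slices, spec, n, duration, dt, rng_inp)

    # flatten recurrent + input edges, grouping synaptic channels by (tau, sign)
    src_list = [e[:, 0] for e in net.edges if len(e)]
    tgt_list = [e[:, 1] for e in net.edges if len(e)]
    w_list = [w for e, w in zip(net.edges, net.edge_weights) if len(e)]
    tau_list = [np.full(len(e), c.synapse_tau)
                for e, c in zip(net.edges, spec.connections) if len(e)]
    if in_edges:
        arr = np.array([(u, t, w) for u, t, w, _ in in_edges], dtype=float)
        src_list.append(arr[:, 0].astype(np.int64))
        tgt_list.append(arr[:, 1].astype(np.int64))
        w_list.append(arr[:, 2])
        tau_list.append(np.array([tau for _, _, _, tau in in_edges]))
    if src_list:
        src = np.concatenate(src_list)
        tgt = np.concatenate(tgt_list)
        wts = np.concatenate(w_list)
        taus = np.concatenate(tau_list)
    else:
        src = np.empty(0, dtype=np.int64)
        tgt = np.empty(0, dtype=np.int64)
        wts = np.empty(0)
        taus = np.empty(0)

    keys = np.stack([taus, np.sign(wts)], axis=1) if len(wts) else np.empty((0, 2))
    uniq, ch = (np.unique(keys, axis=0, return_inverse=True)
                if len(keys) else (np.empty((0, 2)), np.empty(0, dtype=np.int64)))
    beta_ch = np.exp(-dt / uniq[:, 0]) if len(uniq) else np.empty(0)

    order = np.argsort(src, kind="stable")
    src, tgt, wts, ch = src[order], tgt[order], wts[order], ch[order].astype(np.int64)
    indptr = np.zeros(n_units + 1, dtype=np.int64)
    np.add.at(indptr[1:], src, 1)
    indptr = np.cumsum(indptr)

    max_events = int(rate_cap * n * duration) + 64
    from ._engine import run_network

    ev_step, ev_id, overflow, acc_pos, acc_neg = run_network(
        nsteps, n,
        np.exp(-dt / net.tau_m), net.v_thr, net.v_reset,
        np.round(net.refractory / dt).astype(np.int64),
        beta_ch, indptr, tgt.astype(np.int64), wts, ch,
        ext_steps, ext_units, max_events)
    if overflow:
        raise RunawayExcitationError(
            f"event budget exhausted ({max_events} events, cap {rate_cap} Hz/neuron); "
            "network parameters are outside the balanced regime")
    times = (ev_step + 1) * dt
    return SpikeRaster(times, ev_id.astype(np.int64), net.pop_slices, duration,
                       mean_drive_exc=acc_pos / nsteps, mean_drive_inh=acc_neg / nsteps)


def population_rate(raster: SpikeRaster, population: str,
                    window: float = 0.5, step: float | None = None):
    """Sliding-window population rate in Hz per neuron.

    Returns (window center times, rates).  Windows tile [0, duration].
    """
    if step is None:
        step = window
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    lo, hi = raster.pop_slices[population]
    size = hi - lo
    if size == 0:
        raise ValueError(f"population {population!r} is empty")
    t, _ = raster.population_events(population)
    t = np.sort(t)
    starts = np.arange(0.0, raster.duration - window + 1e-12, step)
    counts = np.searchsorted(t, starts + window) - np.searchsorted(t, starts)
    return starts + window / 2.0, counts / (window * size)


def wta_rate_oracle(inputs, gamma: float = 50.0, tau: float = 0.02,
                    t_max: float | None = None, rtol: float = 1e-9):
    """Integrate the winner-take-all firing-rate equations to steady state.

    Dynamics: ``tau * dr_i/dt = -r_i + f(I_i - sum_{j!=i} w_ij r_j)`` with
    rectification ``f`` and state-dependent lateral inhibition
    ``w_ij = gamma * Theta(r_j - r_i)``: only neurons currently losing the
    competition are inhibited.  In the idealized large-gamma regime the
    unique survivor is ``argmax_i I_i``.  Raises :class:`WTATieError` when
    the maximal inputs are tied.

    Returns (winner index, steady-state rates).
    """
    I = np.asarray(inputs, dtype=float)
    if I.ndim != 1 or len(I) < 2:
        raise ValueError("inputs must be a vector of at least two drives")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    imax = np.max(I)
    ties = np.nonzero(I >= imax - rtol * max(abs(imax), 1.0))[0]
    if len(ties) > 1:
        raise WTATieError(f"maximal inputs tied at indices {ties.tolist()}")
    if t_max is None:
        t_max = 60.0 * tau
    dt = tau / 50.0
    r = np.maximum(I, 0.0) * 1e-3  # small seed proportional to drive
    nsteps = int(round(t_max / dt))
    for _ in range(nsteps):
        # w_ij = gamma * Theta(r_j - r_i): inhibition from stronger units
        inh = gamma * np.array([np.sum(r[r > ri]) for ri in r])
        drive = np.maximum(I - inh, 0.0)
        r = r + dt * (-r + drive) / tau
        r = np.maximum(r, 0.0)
    winner = int(np.argmax(r))
    return winner, r
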