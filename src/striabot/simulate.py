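"""Conductance-based LIF network integration.

Membrane dynamics per neuron::

    C_m dV/dt = -g_L (V - V_rest) - g_ex (V - E_ex) - g_in (V - E_in) + I_ext

with exponentially decaying excitatory and inhibitory conductances
(tau_syn_ex, tau_syn_in).  Integration is exponential-Euler: within a step
the conductances are held fixed for the membrane update (which is then the
exact relaxation toward the instantaneous fixed point), and the conductances
themselves decay by their exact exponential factor.  Spikes are detected at
end-of-step threshold crossing; the membrane is reset and held for the
refractory period, while synaptic conductances keep evolving.

Per-step order: (1) deliver conductance increments due this step (delayed
recurrent inhibition, background and stimulus excitation), (2) advance the
membrane, (3) detect spikes and schedule their delayed inhibitory increments,
(4) decay conductances.  Synaptic delays are rounded to integer multiples of
dt (minimum one step).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NetworkSpec
from .params import D2, NEURON_PARAMS, NeuronParameters
from .protocols import StimulusProtocol

__all__ = [
    "SimulationConfig",
    "SpikeData",
    "SimulationError",
    "simulate",
    "poisson_drive",
    "membrane_step",
    "fi_curve",
]


class SimulationError(RuntimeError):
    """Raised when integration produces non-finite state."""


@dataclass(frozen=True)
class SimulationConfig:
    duration: float          # ms
    dt: float = 1.0          # ms
    seed: int = 0
    record_potentials: bool = False
    record_ids: tuple | None = None   # subset for potential recording
    chunk_steps: int = 2000  # batch size for input pre-generation

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one step")


@dataclass
class SpikeData:
    """Timestamped spike events, joinable to the network roster by id."""

    times: np.ndarray     # ms
    ids: np.ndarray
    duration: float       # ms
    n_neurons: int
    potentials: pd.DataFrame | None = None  # optional membrane traces

    def to_dataframe(self, roster: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"neuron_id": self.ids, "time_ms": self.times})
        if roster is not None:
            df = df.merge(roster, left_on="neuron_id", right_on="id",
                          how="left").drop(columns="id")
        return df

    def counts(self) -> np.ndarray:
        """Spike count per neuron id (length n_neurons)."""
        return np.bincount(self.ids, minlength=self.n_neurons)

    def rates(self) -> np.ndarray:
        """Mean rate per neuron in spks/s."""
        return self.counts() / (self.duration / 1000.0)

    def select(self, ids) -> "SpikeData":
        mask = np.isin(self.ids, ids)
        return SpikeData(self.times[mask], self.ids[mask], self.duration,
                         self.n_neurons)

    def binned_counts(self, ids, bin_ms: float) -> np.ndarray:
        """Total spike count of ``ids`` per time bin."""
        sel = self.select(ids)
        n_bins = int(round(self.duration / bin_ms))
        edges = np.arange(n_bins + 1) * bin_ms
        counts, _ = np.histogram(sel.times, bins=edges)
        return counts

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path, duration: float, n_neurons: int) -> "SpikeData":
        df = pd.read_csv(Path(path))
        return cls(df["time_ms"].to_numpy(float),
                   df["neuron_id"].to_numpy(np.int64), duration, n_neurons)


def poisson_drive(rate_hz: float, weight_nS: float, dt: float, rng,
                  n_steps: int, n_neurons: int = 1) -> np.ndarray:
    """Per-step excitatory conductance increments from a Poisson source.

    Event count per step is Poisson(rate * dt); each event adds
    ``weight_nS`` to g_ex.  Independent across neurons.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    lam = rate_hz * dt / 1000.0
    counts = rng.poisson(lam, size=(n_steps, n_neurons))
    return counts * weight_nS


def membrane_step(V, g_ex, g_in, refr, p: dict, I_ext, dt: float):
    """Advance membrane state one step (vectorized over neurons).

    ``p`` holds per-neuron arrays: V_rest, V_thresh, V_reset, g_L, C_m,
    E_ex, E_in, ref_steps.  Returns (V, refr, spiked_mask); conductance
    decay is the caller's responsibility.
    """
    g_tot = p["g_L"] + g_ex + g_in
    V_inf = (p["g_L"] * p["V_rest"] + g_ex * p["E_ex"] + g_in * p["E_in"]
             + I_ext) / g_tot
    decay = np.exp(-g_tot * dt / p["C_m"])
    V_new = V_inf + (V - V_inf) * decay

    active = refr <= 0
    V = np.where(active, V_new, p["V_reset"])
    spiked = active & (V >= p["V_thresh"])
    V = np.where(spiked, p["V_reset"], V)
    refr = np.where(spiked, p["ref_steps"], np.maximum(refr - 1, 0))
    return V, refr, spiked


def _param_arrays(types: np.ndarray, dt: float,
                  neuron_params: dict[str, NeuronParameters]) -> dict:
    is_d2 = (types == D2).astype(int)

    def pick(attr):
        vals = np.array([getattr(neuron_params["D1"], attr),
                         getattr(neuron_params["D2"], attr)], dtype=float)
        return vals[is_d2]

    p = {k: pick(k) for k in ("V_rest", "V_thresh", "V_reset", "g_L",
                              "C_m", "E_ex", "E_in")}
    p["ref_steps"] = np.maximum(
        np.rint(pick("t_ref") / dt), 1).astype(np.int64)
    p["dex"] = np.exp(-dt / pick("tau_syn_ex"))
    p["din"] = np.exp(-dt / pick("tau_syn_in"))
    return p


def _delay_groups(spec: NetworkSpec, dt: float):
    """Group synapses by delay step; CSR (indptr, targets, weights) per group."""
    keep = spec.weight != 0.0
    pre, post = spec.pre[keep], spec.post[keep]
    weight, delay = spec.weight[keep], spec.delay[keep]
    steps = np.maximum(np.rint(delay / dt), 1).astype(np.int64)
    groups = []
    n = spec.n_neurons
    for d in np.unique(steps):
        sel = steps == d
        order = np.argsort(pre[sel], kind="stable")
        sorted_pre = pre[sel][order]
        indptr = np.searchsorted(sorted_pre, np.arange(n + 1))
        groups.append((int(d), indptr, post[sel][order],
                       weight[sel][order]))
    return groups


def _resolve_selector(spec: NetworkSpec, block) -> np.ndarray:
    hemi = None if block.hemisphere == "both" else block.hemisphere
    ct = None if block.cell_type == "both" else block.cell_type
    ids = spec.ids(hemisphere=hemi, cell_type=ct, channels=block.channels)
    if len(ids) == 0:
        raise ValueError(f"protocol block selector matches no neurons: "
                         f"{block}")
    return ids


def simulate(spec: NetworkSpec, protocol: StimulusProtocol | None,
             config: SimulationConfig,
             neuron_params: dict[str, NeuronParameters] | None = None
             ) -> SpikeData:
    """Integrate the network under a stimulation protocol.

    Deterministic given (spec, protocol, config.seed).  ``protocol=None``
    runs background drive only.
    """
    neuron_params = neuron_params or NEURON_PARAMS
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    n = spec.n_neurons
    rng = np.random.default_rng(config.seed)

    types = spec.neurons["type"].to_numpy()
    p = _param_arrays(types, dt, neuron_params)

    mods = protocol.modifiers if protocol is not None else None
    bg_scale = mods.background_scale if mods is not None else 1.0
    inh_scale = mods.inh_weight_scale if mods is not None else 1.0
    inh_scale_step = (int(round(mods.inh_scale_from / dt))
                      if mods is not None else 0)

    # background drive: per-neuron total Poisson rate and weight
    bg_rate = np.empty(n)
    bg_weight = np.empty(n)
    for ct, drive in spec.background.items():
        mask = types == ct
        bg_rate[mask] = drive.total_rate * bg_scale
        bg_weight[mask] = drive.weight_nS
    bg_lam = bg_rate * dt / 1000.0

    # protocol blocks -> step windows and target index arrays
    dc_blocks, poisson_blocks = [], []
    if protocol is not None:
        if protocol.duration > config.duration + 1e-9:
            raise ValueError("protocol is longer than the simulation")
        for b in protocol.blocks:
            if b.t_stop > config.duration + 1e-9:
                raise ValueError(f"protocol block ends at {b.t_stop} ms, "
                                 f"beyond duration {config.duration} ms")
            targets = _resolve_selector(spec, b)
            s0 = int(round(b.t_start / dt))
            s1 = int(round(b.t_stop / dt))
            if b.kind == "dc":
                dc_blocks.append((s0, s1, targets, b.amplitude_pA))
            else:
                lam = b.rate_hz * dt / 1000.0
                poisson_blocks.append((s0, s1, targets, lam, b.weight_nS))

    groups = _delay_groups(spec, dt)
    max_delay = max((d for d, *_ in groups), default=1)
    inh_buf = np.zeros((max_delay + 1, n))

    # DC current profile: build boundary events -> I vector updates
    I_ext = np.zeros(n)
    dc_events: dict[int, list] = {}
    for s0, s1, targets, amp in dc_blocks:
        dc_events.setdefault(s0, []).append((targets, amp))
        dc_events.setdefault(s1, []).append((targets, -amp))

    V = p["V_rest"].copy()
    g_ex = np.zeros(n)
    g_in = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)

    rec_ids = None
    rec_traces = []
    if config.record_potentials:
        rec_ids = (np.asarray(config.record_ids)
                   if config.record_ids is not None else np.arange(n))

    spike_times: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []

    chunk = max(1, config.chunk_steps)
    for c0 in range(0, n_steps, chunk):
        c1 = min(c0 + chunk, n_steps)
        rows = c1 - c0
        # excitatory increments for the chunk: background + stimulus Poisson
        exc_inc = rng.poisson(bg_lam, size=(rows, n)).astype(np.float64)
        exc_inc *= bg_weight
        for s0, s1, targets, lam, w in poisson_blocks:
            lo, hi = max(s0, c0), min(s1, c1)
            if lo < hi:
                counts = rng.poisson(lam, size=(hi - lo, len(targets)))
                exc_inc[lo - c0:hi - c0, targets] += counts * w

        for t in range(c0, c1):
            if t in dc_events:
                for targets, amp in dc_events[t]:
                    I_ext[targets] += amp
            slot = t % (max_delay + 1)
            g_ex += exc_inc[t - c0]
            g_in += inh_buf[slot]
            inh_buf[slot] = 0.0

            V, refr, spiked = membrane_step(V, g_ex, g_in, refr, p, I_ext, dt)

            if spiked.any():
                spikers = np.nonzero(spiked)[0]
                spike_times.append(np.full(len(spikers), (t + 1) * dt))
                spike_ids.append(spikers)
                scale = inh_scale if t >= inh_scale_step else 1.0
                for d, indptr, tgt, w in groups:
                    dest = (t + d) % (max_delay + 1)
                    t_parts = [tgt[indptr[i]:indptr[i + 1]] for i in spikers]
                    all_t = np.concatenate(t_parts)
                    if len(all_t):
                        all_w = np.concatenate(
                            [w[indptr[i]:indptr[i + 1]] for i in spikers])
                        inh_buf[dest] += scale * np.bincount(
                            all_t, weights=all_w, minlength=n)

            g_ex *= p["dex"]
            g_in *= p["din"]

            if rec_ids is not None:
                rec_traces.append(V[rec_ids].copy())

        if not (np.isfinite(V).all() and np.isfinite(g_ex).all()
                and np.isfinite(g_in).all()):
            raise SimulationError(
                f"non-finite state at t = {c1 * dt:.3f} ms")

    times = (np.concatenate(spike_times) if spike_times
             else np.empty(0))
    ids = (np.concatenate(spike_ids) if spike_ids
           else np.empty(0, dtype=np.int64))
    order = np.lexsort((ids, times))
    potentials = None
    if rec_ids is not None:
        potentials = pd.DataFrame(
            np.asarray(rec_traces),
            index=pd.Index((np.arange(n_steps) + 1) * dt, name="time_ms"),
            columns=rec_ids)
    return SpikeData(times[order], ids[order], config.duration, n,
                     potentials=potentials)


def fi_curve(params: NeuronParameters, currents, duration: float = 10_000.0,
             dt: float = 0.1) -> np.ndarray:
    """Firing rate (spks/s) of an isolated neuron vs injected current.

    No background, no synapses; rate = spike count / duration.  Below
    rheobase the rate is exactly zero; above it the curve is
    non-decreasing.
    """
    currents = np.asarray(currents, dtype=float)
    m = len(currents)
    n_steps = int(round(duration / dt))
    arrays = {k: np.full(m, getattr(params, k))
              for k in ("V_rest", "V_thresh", "V_reset", "g_L", "C_m",
                        "E_ex", "E_in")}
    arrays["ref_steps"] = np.full(
        m, max(1, int(round(params.t_ref / dt))), dtype=np.int64)
    V = arrays["V_rest"].copy()
    zeros = np.zeros(m)
    refr = np.zeros(m, dtype=np.int64)
    counts = np.zeros(m, dtype=np.int64)
    for _ in range(n_steps):
        V, refr, spiked = membrane_step(V, zeros, zeros, refr, arrays,
                                        currents, dt)
        counts += spiked
    return counts / (duration / 1000.0)
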