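"""Spike-train and trajectory statistics.

Correlation analyses mimic calcium-imaging measurements: spike trains are
convolved with a 300 ms exponential kernel (the decay time of GCaMP6f
calcium transients) before Pearson correlation.  Pairs are grouped by the
wrapped-grid distance between their channels (within / near / far), matching
the three tiers of the connectivity kernel.

The recruitment analysis quantifies the GABA-antagonist experiment: neurons
recruited only when inhibition is reduced are located relative to their
nearest control-recruited neighbor in wrapped channel distance; the mode of
that distribution discriminates monotonic (mode 0) from non-monotonic
(mode 1, ~40 um) connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motor import exp_filter
from .network import NetworkSpec, torus_distance, distance_category
from .params import D1, D2, ChannelGrid
from .simulate import SpikeData

__all__ = [
    "binned_rates",
    "calcium_filter",
    "spike_matrix",
    "CorrelationSummary",
    "pairwise_correlation_histograms",
    "correlation_matrix_subsample",
    "instantaneous_population_correlation",
    "shuffle_spikes",
    "winning_channel",
    "selected_action",
    "coactive_neurons",
    "RecruitmentResult",
    "recruitment_distance_distribution",
    "mean_corrected_traces",
    "positive_mode",
    "CORRELATION_BINS",
]

CALCIUM_TAU = 300.0  # ms

#: histogram edges giving bin centers on multiples of 0.1 (incl. 0.6)
CORRELATION_BINS = np.round(np.arange(-1.05, 1.15, 0.1), 3)


def binned_rates(spikes: SpikeData, spec: NetworkSpec, bin_ms: float = 200.0,
                 group_by: str = "channel_type") -> pd.DataFrame:
    """Per-group instantaneous rate series, in spks/s per neuron.

    ``group_by``: 'channel_type' (channel x cell type) or
    'hemisphere_type'.  Columns are group labels, index is bin start (ms).
    """
    if group_by not in ("channel_type", "hemisphere_type"):
        raise ValueError(f"unknown group_by {group_by!r}")
    key = "channel" if group_by == "channel_type" else "hemisphere"
    n_bins = int(round(spikes.duration / bin_ms))
    out = {}
    for (g, ct), sub in spikes.to_dataframe(spec.neurons).groupby(
            [key, "type"], sort=True, observed=True):
        counts, _ = np.histogram(sub["time_ms"],
                                 bins=np.arange(n_bins + 1) * bin_ms)
        n_group = int(((spec.neurons[key] == g)
                       & (spec.neurons["type"] == ct)).sum())
        out[f"{g}:{ct}"] = counts / (bin_ms / 1000.0) / n_group
    # groups with no spikes at all -> zero series
    for (g, ct), n_group in spec.neurons.groupby(
            [key, "type"], observed=True).size().items():
        label = f"{g}:{ct}"
        if label not in out:
            warnings.warn(f"group {label} produced no spikes", stacklevel=2)
            out[label] = np.zeros(n_bins)
    return pd.DataFrame(out, index=pd.Index(np.arange(n_bins) * bin_ms,
                                            name="t_ms"))


def spike_matrix(spikes: SpikeData, ids: np.ndarray,
                 dt: float = 1.0) -> np.ndarray:
    """(len(ids), n_steps) per-step spike counts for the given neurons."""
    ids = np.asarray(ids)
    n_steps = int(round(spikes.duration / dt))
    pos = {int(i): k for k, i in enumerate(ids)}
    mask = np.isin(spikes.ids, ids)
    rows = np.fromiter((pos[int(i)] for i in spikes.ids[mask]),
                       dtype=np.int64, count=int(mask.sum()))
    cols = np.minimum((spikes.times[mask] / dt).astype(np.int64),
                      n_steps - 1)
    mat = np.zeros((len(ids), n_steps))
    np.add.at(mat, (rows, cols), 1.0)
    return mat


def calcium_filter(counts: np.ndarray, dt: float = 1.0,
                   tau: float = CALCIUM_TAU) -> np.ndarray:
    """Exponential (calcium-like) filtering of per-step spike counts.

    Same unit-area kernel as the motor filter but with tau = 300 ms; a
    single spike peaks at 1000/tau ~ 3.33 s^-1.  Linear over superposed
    trains.  Works on 1-D or (n_trains, n_steps) arrays.
    """
    return exp_filter(counts, dt, tau)


@dataclass
class CorrelationSummary:
    """Pairwise Pearson coefficients grouped by type pair and distance tier."""

    coefficients: dict[tuple[str, str], np.ndarray]  # (pair, category) -> r
    n_sampled: int
    n_dropped_silent: int
    phase: str = "no_stim"

    def histogram(self, pair: str, category: str,
                  bins=CORRELATION_BINS) -> tuple[np.ndarray, np.ndarray]:
        """Density-normalized histogram (mass sums to 1) and bin centers."""
        r = self.coefficients.get((pair, category), np.empty(0))
        hist, edges = np.histogram(r, bins=bins)
        total = hist.sum()
        dens = hist / total if total else hist.astype(float)
        return dens, (edges[:-1] + edges[1:]) / 2.0


def positive_mode(r: np.ndarray, bins=CORRELATION_BINS) -> float:
    """Location of the histogram mode restricted to positive coefficients."""
    hist, edges = np.histogram(r, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    pos = centers > 0
    if not hist[pos].any():
        raise ValueError("no positive correlation mass")
    return float(centers[pos][np.argmax(hist[pos])])


def _pair_label(t1: str, t2: str) -> str:
    return f"{t1}-{t2}" if (t1, t2) in ((D1, D1), (D2, D2), (D1, D2)) \
        else f"{t2}-{t1}"


def pairwise_correlation_histograms(
        spikes: SpikeData, spec: NetworkSpec, n_sample: int = 500,
        phase_window: tuple[float, float] | None = None,
        transient_ms: float = 500.0, seed=0, dt: float = 1.0,
        hemisphere: str = "L", phase: str = "no_stim") -> CorrelationSummary:
    """Pearson coefficients of filtered spike trains for sampled neuron pairs.

    ``n_sample`` neurons are drawn at random from one hemisphere; all
    unordered distinct pairs are correlated over ``phase_window`` (ms),
    shrunk by ``transient_ms`` on both sides to exclude stimulus on/offset
    transients.  Zero-variance (silent) trains are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    pool = spec.ids(hemisphere=hemisphere)
    if n_sample > len(pool):
        warnings.warn(f"n_sample={n_sample} exceeds population "
                      f"({len(pool)}); using all neurons", stacklevel=2)
        n_sample = len(pool)
    ids = np.sort(rng.choice(pool, size=n_sample, replace=False))

    t0, t1 = phase_window if phase_window else (0.0, spikes.duration)
    t0, t1 = t0 + transient_ms, t1 - transient_ms
    if t1 - t0 < 10 * dt:
        raise ValueError("phase window too short after transient exclusion")

    mat = spike_matrix(spikes, ids, dt)
    traces = calcium_filter(mat, dt)
    lo, hi = int(round(t0 / dt)), int(round(t1 / dt))
    traces = traces[:, lo:hi]

    alive = traces.std(axis=1) > 0
    n_dropped = int((~alive).sum())
    ids, traces = ids[alive], traces[alive]
    r_mat = np.corrcoef(traces)

    meta = spec.neurons.set_index("id").loc[ids]
    types = meta["type"].to_numpy()
    coords = list(zip(meta["row"].to_numpy(), meta["col"].to_numpy()))
    m = len(ids)
    iu, ju = np.triu_indices(m, k=1)
    cats = np.array([
        distance_category(coords[i], coords[j], spec.grid,
                          spec.kernel.neighborhood)
        for i, j in zip(iu, ju)])
    pairs = np.array([_pair_label(types[i], types[j])
                      for i, j in zip(iu, ju)])
    rvals = r_mat[iu, ju]

    coeffs: dict[tuple[str, str], np.ndarray] = {}
    for p in ("D1-D1", "D2-D2", "D1-D2"):
        for c in ("within", "near", "far"):
            coeffs[(p, c)] = rvals[(pairs == p) & (cats == c)]
    return CorrelationSummary(coeffs, n_sampled=m,
                              n_dropped_silent=n_dropped, phase=phase)


def correlation_matrix_subsample(
        spikes: SpikeData, spec: NetworkSpec, stride: int = 5,
        phase_window: tuple[float, float] | None = None,
        transient_ms: float = 0.0, dt: float = 1.0,
        hemisphere: str = "L") -> dict[str, np.ndarray]:
    """Correlation matrices of every ``stride``-th neuron per channel.

    Deterministic subsample (positions 0, stride, 2*stride, ... within each
    channel's D1 and D2 blocks, 8 per channel at the default stride);
    matrices are ordered channel-by-channel so channel-level block structure
    is visible.  Returns {'D1-D1', 'D2-D2', 'D1-D2'} matrices; silent
    neurons yield NaN rows/columns.
    """
    neurons = spec.neurons[spec.neurons["hemisphere"] == hemisphere]
    sel = {}
    for ct in (D1, D2):
        ids = []
        for _, grp in neurons[neurons["type"] == ct].groupby("channel"):
            ids.extend(grp["id"].to_numpy()[::stride])
        sel[ct] = np.array(ids)

    t0, t1 = phase_window if phase_window else (0.0, spikes.duration)
    t0, t1 = t0 + transient_ms, t1 - transient_ms
    lo, hi = int(round(t0 / dt)), int(round(t1 / dt))

    traces = {}
    for ct in (D1, D2):
        tr = calcium_filter(spike_matrix(spikes, sel[ct], dt), dt)[:, lo:hi]
        sd = tr.std(axis=1)
        tr = (tr - tr.mean(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            tr = tr / np.where(sd > 0, sd, np.nan)[:, None]
        traces[ct] = tr

    n_t = traces[D1].shape[1]
    return {
        "D1-D1": traces[D1] @ traces[D1].T / n_t,
        "D2-D2": traces[D2] @ traces[D2].T / n_t,
        "D1-D2": traces[D1] @ traces[D2].T / n_t,
    }


def instantaneous_population_correlation(
        trace_a: np.ndarray, trace_b: np.ndarray, window: float,
        step: float = 100.0, dt: float = 1.0
        ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window Pearson r(t) between two population traces.

    ``window`` and ``step`` in ms; returns (window-center times ms, r).
    """
    n = len(trace_a)
    w = int(round(window / dt))
    if w > n:
        raise ValueError("window longer than the recording")
    s = max(1, int(round(step / dt)))
    starts = np.arange(0, n - w + 1, s)
    r = np.empty(len(starts))
    for k, st in enumerate(starts):
        a = trace_a[st:st + w]
        b = trace_b[st:st + w]
        sa, sb = a.std(), b.std()
        r[k] = (np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
                if sa > 0 and sb > 0 else np.nan)
    centers = (starts + w / 2.0) * dt
    return centers, r


def shuffle_spikes(spikes: SpikeData, rng) -> SpikeData:
    """Shuffle control: redraw each spike time uniformly over the recording.

    Destroys temporal alignment while preserving per-neuron spike counts.
    """
    times = rng.uniform(0.0, spikes.duration, size=len(spikes.times))
    order = np.lexsort((spikes.ids, times))
    return SpikeData(times[order], spikes.ids[order], spikes.duration,
                     spikes.n_neurons)


def winning_channel(counts_a: np.ndarray, counts_b: np.ndarray,
                    labels: tuple[str, str], window: float = 250.0,
                    margin: float = 0.05, dt: float = 1.0) -> np.ndarray:
    """Winner per sliding window from two channels' D2 activity series.

    ``counts_a``/``counts_b`` are per-step D2 spike counts of the two
    channels.  In each 250 ms window the channel with higher summed
    activity wins if the relative difference |A-B| / mean(A, B) exceeds
    ``margin``; otherwise 'none' (no clear winner).
    """
    w = max(1, int(round(window / dt)))
    kernel = np.ones(w)
    a = np.convolve(np.asarray(counts_a, float), kernel, mode="valid")
    b = np.convolve(np.asarray(counts_b, float), kernel, mode="valid")
    denom = (a + b) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(a - b) / denom
    out = np.full(len(a), "none", dtype=object)
    clear = (denom > 0) & (rel > margin)
    out[clear & (a > b)] = labels[0]
    out[clear & (b > a)] = labels[1]
    return out


def selected_action(winners_left: np.ndarray,
                    winners_right: np.ndarray) -> np.ndarray:
    """Action selected when both hemispheres agree on a label, else 'none'."""
    wl, wr = np.asarray(winners_left), np.asarray(winners_right)
    if wl.shape != wr.shape:
        raise ValueError("winner sequences must have equal length")
    agree = (wl == wr) & (wl != "none")
    out = np.full(wl.shape, "none", dtype=object)
    out[agree] = wl[agree]
    return out


def coactive_neurons(spikes: SpikeData, t_start: float,
                     t_stop: float) -> set[int]:
    """Ids of neurons with at least one spike in [t_start, t_stop] ms."""
    m = (spikes.times >= t_start) & (spikes.times <= t_stop)
    return set(int(i) for i in np.unique(spikes.ids[m]))


@dataclass
class RecruitmentResult:
    """Nearest-neighbor channel distances of antagonist-only neurons."""

    control_set: set[int]
    antagonist_only_set: set[int]
    nn_distances: np.ndarray          # channel-distance units
    coactive_counts: dict[str, int] = field(default_factory=dict)

    def distance_histogram(self) -> pd.Series:
        """Counts per discrete channel-distance value."""
        vals, counts = np.unique(np.round(self.nn_distances, 6),
                                 return_counts=True)
        return pd.Series(counts, index=vals)

    def to_um(self, grid: ChannelGrid) -> np.ndarray:
        return self.nn_distances * grid.channel_spacing_um


def recruitment_distance_distribution(
        control_set: set[int], antagonist_set: set[int], spec: NetworkSpec,
        downsample: int = 500, seed=0) -> RecruitmentResult:
    """Distances from antagonist-only neurons to nearest control neurons.

    The recorded population (the full roster) is first down-sampled to
    ``downsample`` neurons — emulating an imaging field of view of ~500
    cells — and the coactive sets are restricted to that sample; each
    sampled neuron recruited only in the antagonist bout is assigned the
    wrapped channel distance to its nearest sampled control neighbor.
    """
    if not control_set:
        raise ValueError("empty control set: no reference neurons")
    rng = np.random.default_rng(seed)
    pool = spec.neurons["id"].to_numpy()
    if len(pool) > downsample:
        pool = np.sort(rng.choice(pool, size=downsample, replace=False))
    kept = set(int(i) for i in pool)
    ctrl = sorted(control_set & kept)
    anta_only = sorted((antagonist_set - control_set) & kept)
    if not ctrl:
        raise ValueError("down-sampling removed all control neurons")

    chan = spec.neurons.set_index("id")["channel"]
    ctrl_coords = [spec.grid.coord(int(c)) for c in chan.loc[ctrl]]
    dists = []
    for nid in anta_only:
        c0 = spec.grid.coord(int(chan.loc[nid]))
        dists.append(min(torus_distance(c0, c, spec.grid)
                         for c in set(ctrl_coords)))
    return RecruitmentResult(
        control_set=set(ctrl),
        antagonist_only_set=set(anta_only),
        nn_distances=np.array(dists),
        coactive_counts={"control": len(control_set),
                         "antagonist": len(antagonist_set)})


def mean_corrected_traces(traces: np.ndarray,
                          axis: int = -1) -> np.ndarray:
    """Subtract each trace's mean over the window (correlation-invariant)."""
    traces = np.asarray(traces, dtype=float)
    return traces - traces.mean(axis=axis, keepdims=True)
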