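"""Construction of the two-hemisphere striatal network.

Each hemisphere holds 36 channels x (40 D1 + 40 D2) = 2880 MSNs on the
wrapped 6x6 grid.  Ordered neuron pairs are connected independently with a
probability rho(pre_type, post_type) * k(distance category); all synapses are
inhibitory, with a conductance magnitude set by the type pair and a delay set
by the distance category.  There are no interhemispheric connections.

Neuron ids are channel-major and deterministic: within a hemisphere, channel
``ch`` owns ids ``[offset + 80*ch, offset + 80*ch + 40)`` for D1 and the next
40 for D2, which makes deterministic sub-sampling (e.g. every 5th neuron)
reproducible across builds.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import (ACTION_CHANNELS, BACKGROUND, CELL_TYPES, ChannelGrid,
                     ConnectivityKernel, D1, D2, HEMISPHERES)

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkSpec",
    "torus_distance",
    "distance_category",
    "scaled_probability",
    "build_hemisphere",
    "build_network",
    "sever_connections",
]

NEURONS_PER_CHANNEL = {D1: 40, D2: 40}


def torus_distance(c1, c2, grid: ChannelGrid) -> float:
    """Euclidean distance between channel coordinates with wrapped axes.

    Each axis difference is wrapped to ``min(|d|, L - |d|)`` before the
    Euclidean combination, so the maximal distance on the default 6x6 grid
    is sqrt(18).
    """
    r1, c1_ = grid.validate(c1)
    r2, c2_ = grid.validate(c2)
    dr = abs(r1 - r2)
    dc = abs(c1_ - c2_)
    if grid.wrap:
        dr = min(dr, grid.rows - dr)
        dc = min(dc, grid.cols - dc)
    return math.hypot(dr, dc)


def distance_category(c1, c2, grid: ChannelGrid, neighborhood: int = 8) -> str:
    """Classify a channel pair as 'within', 'near' or 'far'.

    'near' is the immediate neighborhood: the 8 surrounding cells
    (wrapped d <= sqrt(2)) by default, or the 4 axial neighbors (d <= 1)
    when ``neighborhood=4``.
    """
    d = torus_distance(c1, c2, grid)
    if d == 0.0:
        return "within"
    cutoff = math.sqrt(2) if neighborhood == 8 else 1.0
    return "near" if d <= cutoff + 1e-12 else "far"


def scaled_probability(pre_type: str, post_type: str, category: str,
                       kernel: ConnectivityKernel) -> float:
    """Connection probability rho(pre, post) * k(category), clipped at 1."""
    try:
        rho = kernel.rho[(pre_type, post_type)]
    except KeyError:
        raise ValueError(
            f"no connection probability configured for "
            f"{pre_type}->{post_type}") from None
    p = rho * kernel.k(category)
    if p > 1.0:
        logger.warning("scaled probability %.3f for %s->%s (%s) clipped to 1",
                       p, pre_type, post_type, category)
        p = 1.0
    return p


@dataclass
class NetworkSpec:
    """Explicit roster + synapse list for one or two hemispheres.

    ``neurons`` columns: id, hemisphere, type, row, col, channel.
    Synapses are stored as parallel arrays (pre id, post id, conductance
    magnitude in nS, delay in ms); all are inhibitory.
    """

    neurons: pd.DataFrame
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray       # nS, magnitude (inhibitory)
    delay: np.ndarray        # ms
    grid: ChannelGrid
    kernel: ConnectivityKernel
    background: dict = field(default_factory=lambda: dict(BACKGROUND))
    action_channels: dict = field(default_factory=lambda: dict(ACTION_CHANNELS))

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    # -- selection helpers ------------------------------------------------
    def ids(self, hemisphere: str | None = None, cell_type: str | None = None,
            channels=None) -> np.ndarray:
        """Neuron ids matching hemisphere / type / channel-coordinate filters."""
        mask = np.ones(self.n_neurons, dtype=bool)
        if hemisphere is not None:
            mask &= self.neurons["hemisphere"].to_numpy() == hemisphere
        if cell_type is not None:
            mask &= self.neurons["type"].to_numpy() == cell_type
        if channels is not None:
            chan_idx = {self.grid.index(c) for c in channels}
            mask &= np.isin(self.neurons["channel"].to_numpy(),
                            sorted(chan_idx))
        return self.neurons.loc[mask, "id"].to_numpy()

    def copy(self) -> "NetworkSpec":
        return NetworkSpec(self.neurons.copy(), self.pre.copy(),
                           self.post.copy(), self.weight.copy(),
                           self.delay.copy(), self.grid, self.kernel,
                           dict(self.background), dict(self.action_channels))

    # -- persistence -------------------------------------------------------
    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.neurons.to_csv(directory / "neurons.csv", index=False)
        pd.DataFrame({"pre": self.pre, "post": self.post,
                      "conductance_nS": self.weight,
                      "delay_ms": self.delay}).to_csv(
            directory / "synapses.csv", index=False)

    @classmethod
    def from_csv(cls, directory, grid: ChannelGrid | None = None,
                 kernel: ConnectivityKernel | None = None) -> "NetworkSpec":
        directory = Path(directory)
        neurons = pd.read_csv(directory / "neurons.csv")
        syn = pd.read_csv(directory / "synapses.csv")
        return cls(neurons, syn["pre"].to_numpy(), syn["post"].to_numpy(),
                   syn["conductance_nS"].to_numpy(float),
                   syn["delay_ms"].to_numpy(float),
                   grid or ChannelGrid(),
                   kernel or ConnectivityKernel.default())


def _roster(grid: ChannelGrid, hemisphere: str, id_offset: int) -> pd.DataFrame:
    per_channel = sum(NEURONS_PER_CHANNEL.values())
    rows, cols, chans, types = [], [], [], []
    for ch in range(grid.n_channels):
        r, c = grid.coord(ch)
        for cell_type in CELL_TYPES:
            n = NEURONS_PER_CHANNEL[cell_type]
            rows += [r] * n
            cols += [c] * n
            chans += [ch] * n
            types += [cell_type] * n
    n_total = grid.n_channels * per_channel
    return pd.DataFrame({
        "id": np.arange(id_offset, id_offset + n_total),
        "hemisphere": hemisphere,
        "type": types,
        "row": np.array(rows, dtype=np.int64),
        "col": np.array(cols, dtype=np.int64),
        "channel": np.array(chans, dtype=np.int64),
    })


def _category_matrix(grid: ChannelGrid, neighborhood: int) -> np.ndarray:
    """(n_channels, n_channels) codes: 0=within, 1=near, 2=far."""
    n = grid.n_channels
    codes = np.empty((n, n), dtype=np.int8)
    lut = {"within": 0, "near": 1, "far": 2}
    for i in range(n):
        for j in range(n):
            codes[i, j] = lut[distance_category(grid.coord(i), grid.coord(j),
                                                grid, neighborhood)]
    return codes


def build_hemisphere(grid: ChannelGrid, kernel: ConnectivityKernel,
                     seed, hemisphere: str = "L",
                     id_offset: int = 0) -> NetworkSpec:
    """Sample one hemisphere's synapses (directed, no autapses/multapses)."""
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
    rng = np.random.default_rng(seed)
    neurons = _roster(grid, hemisphere, id_offset)
    n = len(neurons)
    type_is_d2 = (neurons["type"].to_numpy() == D2)
    channel = neurons["channel"].to_numpy()

    cat = _category_matrix(grid, kernel.neighborhood)[
        np.ix_(channel, channel)]  # (n, n) int8

    # probability per ordered pair: rho[type_pre, type_post] * k[category]
    k_by_cat = np.array([kernel.k("within"), kernel.k("near"),
                         kernel.k("far")])
    rho_tbl = np.empty((2, 2))
    j_tbl = np.empty((2, 2))
    for (pre_t, post_t), rho in kernel.rho.items():
        rho_tbl[int(pre_t == D2), int(post_t == D2)] = rho
    for (pre_t, post_t), j in kernel.J.items():
        j_tbl[int(pre_t == D2), int(post_t == D2)] = abs(j)

    prob = (rho_tbl[type_is_d2.astype(int)[:, None],
                    type_is_d2.astype(int)[None, :]]
            * k_by_cat[cat])
    if prob.max() > 1.0:
        logger.warning("scaled probabilities clipped at 1.0 during build")
        np.clip(prob, 0.0, 1.0, out=prob)
    mask = rng.random((n, n)) < prob
    np.fill_diagonal(mask, False)

    pre_idx, post_idx = np.nonzero(mask)
    weight = j_tbl[type_is_d2[pre_idx].astype(int),
                   type_is_d2[post_idx].astype(int)]
    delay_by_cat = np.array([kernel.delay_within, kernel.delay_near,
                             kernel.delay_far])
    delay = delay_by_cat[cat[pre_idx, post_idx]]

    ids = neurons["id"].to_numpy()
    return NetworkSpec(neurons, ids[pre_idx], ids[post_idx],
                       weight.astype(np.float64), delay.astype(np.float64),
                       grid, kernel)


def build_network(grid: ChannelGrid | None = None,
                  kernel: ConnectivityKernel | None = None,
                  seed=0) -> NetworkSpec:
    """Build both hemispheres with independent seed streams; no crossings."""
    grid = grid or ChannelGrid()
    kernel = kernel or ConnectivityKernel.default()
    left_seed, right_seed = np.random.SeedSequence(seed).spawn(2)
    left = build_hemisphere(grid, kernel, left_seed, "L", 0)
    right = build_hemisphere(grid, kernel, right_seed, "R", left.n_neurons)
    neurons = pd.concat([left.neurons, right.neurons], ignore_index=True)
    return NetworkSpec(neurons,
                       np.concatenate([left.pre, right.pre]),
                       np.concatenate([left.post, right.post]),
                       np.concatenate([left.weight, right.weight]),
                       np.concatenate([left.delay, right.delay]),
                       grid, kernel)


def sever_connections(spec: NetworkSpec, pre_type: str, post_type: str,
                      channel_pair) -> NetworkSpec:
    """Zero the weights of ``pre_type -> post_type`` synapses crossing
    between the two channels of ``channel_pair`` (both directions, within
    each hemisphere).  Within-channel synapses are untouched.  Returns a
    modified copy; idempotent.
    """
    ch_a, ch_b = channel_pair
    ia, ib = spec.grid.index(ch_a), spec.grid.index(ch_b)
    if ia == ib:
        raise ValueError("channel pair must name two distinct channels")
    out = spec.copy()
    by_id_channel = out.neurons.set_index("id")["channel"]
    by_id_type = out.neurons.set_index("id")["type"]
    pre_ch = by_id_channel.loc[out.pre].to_numpy()
    post_ch = by_id_channel.loc[out.post].to_numpy()
    type_ok = ((by_id_type.loc[out.pre].to_numpy() == pre_type)
               & (by_id_type.loc[out.post].to_numpy() == post_type))
    cross = (((pre_ch == ia) & (post_ch == ib))
             | ((pre_ch == ib) & (post_ch == ia)))
    sel = type_ok & cross
    if not sel.any():
        warnings.warn("sever_connections: selection matched no synapses",
                      stacklevel=2)
    out.weight = out.weight.copy()
    out.weight[sel] = 0.0
    return out
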