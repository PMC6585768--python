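"""Model parameters for the two-hemisphere striatal network.

The network is composed of D1- and D2-type medium spiny neurons (MSNs),
modelled as conductance-based leaky integrate-and-fire units.  Membrane and
synaptic constants differ between the two types: D1-MSNs have a more
hyperpolarized rest, larger capacitance and larger leak conductance, making
them less excitable than D2-MSNs (rheobase 334.8 pA vs 159.3 pA).

Channels (striatal functional units of 40 D1 + 40 D2 MSNs each) live on a
6x6 grid with wrapped edges.  Connection probabilities between MSN pairs are
type-specific base values scaled by a distance-dependent kernel that, in its
default non-monotonic form, peaks for *neighboring* channels rather than
within a channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "NeuronParameters",
    "ChannelGrid",
    "ConnectivityKernel",
    "MotorParameters",
    "D1",
    "D2",
    "NEURON_PARAMS",
    "BACKGROUND",
    "ACTION_CHANNELS",
]

D1 = "D1"
D2 = "D2"
CELL_TYPES = (D1, D2)
HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class NeuronParameters:
    """Conductance-based LIF constants for one MSN type.

    ``E_ex``, ``E_in``, ``V_reset`` and ``t_ref`` are the conventional
    conductance-LIF completions of the published membrane constants
    (excitatory reversal 0 mV, inhibitory reversal -85 mV, reset -60 mV,
    2 ms refractoriness — the standard defaults of conductance-based LIF
    simulators); all are configurable.
    """

    V_rest: float       # mV
    V_thresh: float     # mV
    C_m: float          # pF
    g_L: float          # nS
    tau_syn_ex: float   # ms
    tau_syn_in: float   # ms
    E_ex: float = 0.0   # mV
    E_in: float = -85.0  # mV
    V_reset: float = -60.0  # mV
    t_ref: float = 2.0  # ms

    def __post_init__(self) -> None:
        if not self.V_rest < self.V_thresh:
            raise ValueError("require V_rest < V_thresh")
        if self.C_m <= 0 or self.g_L <= 0:
            raise ValueError("C_m and g_L must be positive")
        if self.tau_syn_ex <= 0 or self.tau_syn_in <= 0:
            raise ValueError("synaptic time constants must be positive")
        if not (self.E_in < self.V_thresh < self.E_ex):
            raise ValueError("require E_in < V_thresh < E_ex")

    @property
    def rheobase(self) -> float:
        """Minimal constant current (pA) that reaches threshold."""
        return self.g_L * (self.V_thresh - self.V_rest)


#: Published membrane constants per MSN type.
NEURON_PARAMS: dict[str, NeuronParameters] = {
    D1: NeuronParameters(V_rest=-87.2, V_thresh=-50.0, C_m=195.0, g_L=9.0,
                         tau_syn_ex=5.0, tau_syn_in=10.0),
    D2: NeuronParameters(V_rest=-85.4, V_thresh=-50.0, C_m=159.0, g_L=4.5,
                         tau_syn_ex=5.0, tau_syn_in=10.0),
}

@dataclass(frozen=True)
class BackgroundDrive:
    """Excitatory background: a pool of independent Poisson afferents.

    Each neuron receives ``n_sources`` independent trains of ``rate_hz``
    spks/s each at weight ``weight_nS`` (their superposition is Poisson at
    the summed rate).  The pool size is chosen so baseline MSN rates fall
    in the sub-Hz-to-few-Hz in-vivo range with the D1 population firing
    below the D2 population; a single train at these rates and weight
    cannot depolarize an MSN to within fluctuation range of threshold.
    """

    rate_hz: float
    weight_nS: float = 2.5
    n_sources: int = 4

    def __post_init__(self) -> None:
        if self.rate_hz < 0 or self.weight_nS <= 0 or self.n_sources < 1:
            raise ValueError("invalid background drive")

    @property
    def total_rate(self) -> float:
        return self.rate_hz * self.n_sources


#: Background drive per target type.  D1-MSNs receive a higher per-train
#: rate to offset their lower excitability and heavier D2->D1 inhibition,
#: but are still tuned to fire below the D2 population rate.
BACKGROUND: dict[str, BackgroundDrive] = {
    D1: BackgroundDrive(rate_hz=80.0),
    D2: BackgroundDrive(rate_hz=57.0),
}

#: Designated action channels (row, col), identical in both hemispheres and
#: adjacent on the grid.  Encoding is contralateral: the right hemisphere's
#: 'turn_left' channel drives the left action command and vice versa.
ACTION_CHANNELS: dict[str, tuple[int, int]] = {
    "turn_left": (2, 2),
    "turn_right": (2, 3),
}


@dataclass(frozen=True)
class ChannelGrid:
    """Edge-wrapped grid of striatal channels (one candidate action each)."""

    rows: int = 6
    cols: int = 6
    wrap: bool = True
    channel_spacing_um: float = 40.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def index(self, coord: tuple[int, int]) -> int:
        r, c = self.validate(coord)
        return r * self.cols + c

    def coord(self, index: int) -> tuple[int, int]:
        if not 0 <= index < self.n_channels:
            raise ValueError(f"channel index {index} out of range")
        return divmod(index, self.cols)

    def validate(self, coord: tuple[int, int]) -> tuple[int, int]:
        r, c = coord
        if not (0 <= r < self.rows and 0 <= c < self.cols):
            raise ValueError(f"coordinate {coord!r} outside "
                             f"{self.rows}x{self.cols} grid")
        return int(r), int(c)


# type-pair keyed tables; key is (pre_type, post_type)
_RHO = {(D1, D1): 0.07, (D2, D1): 0.13, (D1, D2): 0.05, (D2, D2): 0.23}
_J = {(D1, D1): 0.75, (D2, D1): 1.70, (D1, D2): 0.85, (D2, D2): 1.35}


@dataclass(frozen=True)
class ConnectivityKernel:
    """Distance-dependent scaling of base MSN->MSN connection probabilities.

    ``mode='non_monotonic'`` (default) places the connectivity peak on
    neighboring channels (k_near > k_within), consistent with MSN-MSN
    connectivity peaking at ~40-60 um; ``mode='monotonic'`` swaps k_within
    and k_near so connectivity decays from distance zero.

    All intra-striatal synapses are GABAergic: ``J`` stores the conductance
    magnitude in nS routed to the inhibitory synapse (reversal E_in).
    """

    rho: dict[tuple[str, str], float] = field(default_factory=lambda: dict(_RHO))
    J: dict[tuple[str, str], float] = field(default_factory=lambda: dict(_J))
    k_within: float = 1.2
    k_near: float = 3.4
    k_far: float = 0.3
    delay_within: float = 1.0  # ms
    delay_near: float = 2.5   # ms
    delay_far: float = 4.5    # ms
    mode: str = "non_monotonic"
    neighborhood: int = 8  # 'near' = 8 surrounding cells (4 for von Neumann)

    def __post_init__(self) -> None:
        if self.mode not in ("non_monotonic", "monotonic"):
            raise ValueError(f"unknown kernel mode {self.mode!r}")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        if min(self.delay_within, self.delay_near, self.delay_far) <= 0:
            raise ValueError("delays must be positive")
        for tp, j in self.J.items():
            if abs(j) <= 0:
                raise ValueError(f"zero synaptic conductance for {tp}")

    @classmethod
    def default(cls, mode: str = "non_monotonic") -> "ConnectivityKernel":
        kern = cls(mode=mode)
        if mode == "monotonic":
            # swap within/near scale factors; far unchanged
            kern = replace(kern, k_within=3.4, k_near=1.2)
        return kern

    def k(self, category: str) -> float:
        try:
            return {"within": self.k_within, "near": self.k_near,
                    "far": self.k_far}[category]
        except KeyError:
            raise ValueError(f"unknown distance category {category!r}") from None

    def delay(self, category: str) -> float:
        try:
            return {"within": self.delay_within, "near": self.delay_near,
                    "far": self.delay_far}[category]
        except KeyError:
            raise ValueError(f"unknown distance category {category!r}") from None


@dataclass(frozen=True)
class MotorParameters:
    """Spike-to-motor transformation constants.

    Population rates are low-pass filtered with an exponential kernel
    (tau_motor); D1 activity is weighted more strongly than D2 (S_D1 > S_D2)
    to compensate for the lower D1 firing rate.  The sigmoid bounds each
    action command to (0, 2), which caps linear velocity at v_max = 2 m/s.
    """

    S_D1: float = 2.0
    S_D2: float = 0.4
    N_D1: int = 40
    N_D2: int = 40
    tau_motor: float = 200.0  # ms
    v_max: float = 2.0        # m/s

    def __post_init__(self) -> None:
        if min(self.S_D1, self.S_D2, self.N_D1, self.N_D2,
               self.tau_motor, self.v_max) <= 0:
            raise ValueError("all motor parameters must be positive")
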