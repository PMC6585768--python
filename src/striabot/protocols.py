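"""Stimulation paradigms.

Two families of experiments are encoded here:

* *Global* paradigms — DC current injections to entire D1 and/or D2
  populations of one or both hemispheres, emulating optogenetic
  excitation/inhibition (freezing, ambulation, turning).  The current is on
  from 5 s to 15 s of a 20 s run.
* *Channel* paradigms — excitatory Poisson spike-train input to the
  designated action channels, emulating cortical command sequences
  ('sequences') or two simultaneously requested actions
  ('competing_actions').

The GABA-antagonist experiment (network-connectivity validation) delivers a
140 pA pulse to every neuron for 200 ms at 5 s (control) and again at 15 s
with all inhibitory weights scaled to 20% (antagonist), against background
reduced to 25% to mimic the low spontaneous activity of a slice.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .params import ACTION_CHANNELS

__all__ = [
    "StimulusBlock",
    "Modifiers",
    "StimulusProtocol",
    "GLOBAL_PARADIGMS",
    "SEQUENCE_PARADIGMS",
    "make_global_paradigm",
    "make_sequence_paradigm",
    "make_gaba_experiment",
    "make_paradigm",
    "paradigm_catalog",
]


@dataclass(frozen=True)
class StimulusBlock:
    """One timed input block targeting a population selector.

    ``kind='dc'`` injects ``amplitude_pA``; ``kind='poisson'`` adds an
    independent excitatory Poisson train per targeted neuron with
    ``rate_hz`` and synaptic weight ``weight_nS``.
    ``hemisphere``/``cell_type`` may be 'L', 'R' or 'both' / 'D1', 'D2' or
    'both'; ``channels`` is a list of (row, col) or None for all channels.
    """

    hemisphere: str
    cell_type: str
    kind: str
    t_start: float  # ms
    t_stop: float   # ms
    channels: tuple | None = None
    amplitude_pA: float = 0.0
    rate_hz: float = 0.0
    weight_nS: float = 2.5  # stimulus synapse reuses the background weight

    def __post_init__(self) -> None:
        if self.kind not in ("dc", "poisson"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if not self.t_start < self.t_stop:
            raise ValueError("require t_start < t_stop")
        if self.kind == "poisson" and self.rate_hz < 0:
            raise ValueError("poisson rate must be >= 0")


@dataclass(frozen=True)
class Modifiers:
    """Network-level modifications applied around a protocol.

    ``inh_weight_scale`` multiplies all inhibitory synaptic weights from
    ``inh_scale_from`` (ms) onward; ``background_scale`` multiplies the
    background Poisson rates for the whole run; ``sever_d2d2`` zeroes the
    D2->D2 weights between the two action channels before the run.
    """

    inh_weight_scale: float = 1.0
    inh_scale_from: float = 0.0  # ms
    background_scale: float = 1.0
    sever_d2d2: bool = False


@dataclass(frozen=True)
class StimulusProtocol:
    name: str
    duration: float  # ms
    blocks: tuple[StimulusBlock, ...] = ()
    modifiers: Modifiers = field(default_factory=Modifiers)

    def __post_init__(self) -> None:
        for b in self.blocks:
            if b.t_stop > self.duration + 1e-9:
                raise ValueError(
                    f"block ends at {b.t_stop} ms, beyond protocol "
                    f"duration {self.duration} ms")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for b in d["blocks"]:
            if b["channels"] is not None:
                b["channels"] = [list(c) for c in b["channels"]]
        d["blocks"] = list(d["blocks"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        blocks = []
        for b in d.get("blocks", []):
            b = dict(b)
            if b.get("channels") is not None:
                b["channels"] = tuple(tuple(c) for c in b["channels"])
            blocks.append(StimulusBlock(**b))
        mods = Modifiers(**d.get("modifiers", {}))
        return cls(name=d["name"], duration=d["duration"],
                   blocks=tuple(blocks), modifiers=mods)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StimulusProtocol":
        return cls.from_dict(yaml.safe_load(text))


# (hemisphere, cell_type) -> current pA, per paradigm; applied to all 36
# channels of the stated hemisphere on [5 s, 15 s] of a 20 s run.
GLOBAL_PARADIGMS: dict[str, dict[tuple[str, str], float]] = {
    "no_stim": {},
    "bilateral_D1": {("both", "D1"): 115.0},
    "bilateral_D2": {("both", "D2"): 160.0},
    "unilateral_D1D2_inh": {("L", "D1"): -175.0, ("L", "D2"): -100.0},
    "unilateral_D1_inh": {("L", "D1"): -175.0},
    "unilateral_D2_inh": {("L", "D2"): -100.0},
    "unilateral_D1_exc": {("L", "D1"): 125.0},
    "unilateral_D2_exc": {("L", "D2"): 110.0},
}

# channel-targeted Poisson rates (spks/s) per cell type, per paradigm
SEQUENCE_PARADIGMS: dict[str, dict[str, float]] = {
    "sequences_D1": {"D1": 300.0},
    "sequences_D2": {"D2": 120.0},
    "sequences_D1D2": {"D1": 300.0, "D2": 150.0},
    "competing_actions": {"D1": 250.0, "D2": 200.0},
}

GLOBAL_STIM_WINDOW = (5_000.0, 15_000.0)  # ms
GLOBAL_DURATION = 20_000.0                # ms
SEQUENCE_PHASE = 5_000.0                  # ms per phase, first phase at 5 s
COMPETING_WINDOW = (2_000.0, 18_000.0)    # ms


def make_global_paradigm(name: str, duration: float = GLOBAL_DURATION,
                         stim_window=GLOBAL_STIM_WINDOW) -> StimulusProtocol:
    """DC-injection paradigm from the global catalog."""
    if name not in GLOBAL_PARADIGMS:
        raise KeyError(f"unknown global paradigm {name!r}; valid names: "
                       f"{sorted(GLOBAL_PARADIGMS)}")
    t0, t1 = stim_window
    blocks = tuple(
        StimulusBlock(hemisphere=hemi, cell_type=ct, kind="dc",
                      t_start=t0, t_stop=t1, amplitude_pA=amp)
        for (hemi, ct), amp in GLOBAL_PARADIGMS[name].items())
    return StimulusProtocol(name=name, duration=duration, blocks=blocks)


def make_sequence_paradigm(name: str, duration: float = GLOBAL_DURATION,
                           action_channels=None,
                           stim_weight_nS: float = 2.5) -> StimulusProtocol:
    """Channel-targeted Poisson paradigm from the sequence catalog.

    Sequences drive the left hemisphere's 'turn_right' channel for 5 s
    (from 5 s) and then the right hemisphere's 'turn_left' channel for 5 s;
    'competing_actions' drives both action channels of both hemispheres
    simultaneously from 2 s to 18 s.
    """
    if name not in SEQUENCE_PARADIGMS:
        raise KeyError(f"unknown sequence paradigm {name!r}; valid names: "
                       f"{sorted(SEQUENCE_PARADIGMS)}")
    ac = dict(action_channels or ACTION_CHANNELS)
    rates = SEQUENCE_PARADIGMS[name]
    blocks = []
    if name == "competing_actions":
        t0, t1 = COMPETING_WINDOW
        for ct, rate in rates.items():
            blocks.append(StimulusBlock(
                hemisphere="both", cell_type=ct, kind="poisson",
                t_start=t0, t_stop=t1,
                channels=(tuple(ac["turn_left"]), tuple(ac["turn_right"])),
                rate_hz=rate, weight_nS=stim_weight_nS))
    else:
        phases = [("L", "turn_right", 5_000.0),
                  ("R", "turn_left", 5_000.0 + SEQUENCE_PHASE)]
        for hemi, chan, t0 in phases:
            for ct, rate in rates.items():
                blocks.append(StimulusBlock(
                    hemisphere=hemi, cell_type=ct, kind="poisson",
                    t_start=t0, t_stop=t0 + SEQUENCE_PHASE,
                    channels=(tuple(ac[chan]),),
                    rate_hz=rate, weight_nS=stim_weight_nS))
    return StimulusProtocol(name=name, duration=duration,
                            blocks=tuple(blocks))


def make_gaba_experiment(kernel_mode: str = "non_monotonic",
                         duration: float = GLOBAL_DURATION,
                         stim_pA: float = 140.0) -> StimulusProtocol:
    """Antidromic-stimulation protocol with a simulated GABA antagonist.

    Identical 140 pA / 200 ms pulses to all neurons at 5 s (control) and
    15 s (antagonist); inhibitory weights are scaled to 0.2 from 10 s (the
    midpoint between the pulses) so only the second pulse sees reduced
    inhibition; background runs at 25% throughout.  ``kernel_mode`` is
    carried in the name for bookkeeping; the kernel itself is a property of
    the network build.
    """
    if kernel_mode not in ("monotonic", "non_monotonic"):
        raise ValueError(f"unknown kernel mode {kernel_mode!r}")
    pulses = tuple(
        StimulusBlock(hemisphere="both", cell_type="both", kind="dc",
                      t_start=t0, t_stop=t0 + 200.0, amplitude_pA=stim_pA)
        for t0 in (5_000.0, 15_000.0))
    mods = Modifiers(inh_weight_scale=0.2, inh_scale_from=10_000.0,
                     background_scale=0.25)
    return StimulusProtocol(name=f"gaba_antagonist_{kernel_mode}",
                            duration=duration, blocks=pulses, modifiers=mods)


def make_paradigm(name: str, **kwargs) -> StimulusProtocol:
    """Look up a paradigm by name across both catalogs."""
    if name in GLOBAL_PARADIGMS:
        return make_global_paradigm(name, **kwargs)
    if name in SEQUENCE_PARADIGMS:
        return make_sequence_paradigm(name, **kwargs)
    raise KeyError(f"unknown paradigm {name!r}; valid names: "
                   f"{sorted(GLOBAL_PARADIGMS) + sorted(SEQUENCE_PARADIGMS)}")


def paradigm_catalog() -> dict[str, dict]:
    """Field-for-field table of all paradigms (for listing and golden tests)."""
    catalog: dict[str, dict] = {}
    for name, currents in GLOBAL_PARADIGMS.items():
        catalog[name] = {"kind": "dc",
                         "currents_pA": {f"{h}:{t}": a
                                         for (h, t), a in currents.items()},
                         "window_s": [GLOBAL_STIM_WINDOW[0] / 1000,
                                      GLOBAL_STIM_WINDOW[1] / 1000]}
    for name, rates in SEQUENCE_PARADIGMS.items():
        catalog[name] = {"kind": "poisson", "rates_hz": dict(rates)}
    return catalog
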