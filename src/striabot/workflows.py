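"""End-to-end experiment pipelines: build -> simulate -> motor -> analysis.

These functions reproduce the study's experiment designs at their stated
conditions (20 s behavioral runs, 5-trial repeats with seed+trial_index,
longer runs for correlation estimates) and are shared by the CLI, the test
suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import analysis
from .motor import run_robot
from .network import NetworkSpec, build_hemisphere, build_network, \
    sever_connections
from .params import ChannelGrid, ConnectivityKernel, D2
from .protocols import StimulusProtocol, make_gaba_experiment, make_paradigm
from .simulate import SimulationConfig, SpikeData, simulate

__all__ = [
    "ParadigmRun",
    "run_paradigm",
    "gaba_recruitment_trial",
    "recruitment_experiment",
    "background_correlation_summary",
]


@dataclass
class ParadigmRun:
    spec: NetworkSpec
    protocol: StimulusProtocol
    spikes: SpikeData
    trajectory: pd.DataFrame | None


def run_paradigm(name: str, seed: int = 0,
                 kernel_mode: str = "non_monotonic",
                 duration: float | None = None, dt: float = 1.0,
                 sever_d2d2: bool = False,
                 with_robot: bool = True) -> ParadigmRun:
    """Build the two-hemisphere network and run one named paradigm.

    ``sever_d2d2`` zeroes the D2->D2 weights between the two action
    channels before simulation (used with 'competing_actions').
    """
    kernel = ConnectivityKernel.default(kernel_mode)
    spec = build_network(ChannelGrid(), kernel, seed=seed)
    kwargs = {} if duration is None else {"duration": duration}
    protocol = make_paradigm(name, **kwargs)
    if sever_d2d2:
        spec = sever_connections(
            spec, D2, D2, (spec.action_channels["turn_left"],
                           spec.action_channels["turn_right"]))
    config = SimulationConfig(duration=protocol.duration, dt=dt, seed=seed)
    spikes = simulate(spec, protocol, config)
    traj = run_robot(spikes, spec, dt=dt) if with_robot else None
    return ParadigmRun(spec, protocol, spikes, traj)


def gaba_recruitment_trial(kernel_mode: str, seed: int,
                           downsample: int = 500,
                           dt: float = 1.0) -> analysis.RecruitmentResult:
    """One antidromic-stimulation trial on a single hemisphere (slice).

    Control bout at 5 s, antagonist bout (inhibition at 20%) at 15 s, both
    200 ms at 140 pA; background at 25% throughout.  Returns the
    nearest-neighbor recruitment distances of antagonist-only neurons.
    """
    kernel = ConnectivityKernel.default(kernel_mode)
    spec_h = build_hemisphere(ChannelGrid(), kernel, seed=seed)
    protocol = make_gaba_experiment(kernel_mode)
    spikes = simulate(spec_h, protocol,
                      SimulationConfig(duration=protocol.duration, dt=dt,
                                       seed=seed))
    bouts = [(b.t_start, b.t_stop) for b in protocol.blocks]
    control = analysis.coactive_neurons(spikes, *bouts[0])
    antagonist = analysis.coactive_neurons(spikes, *bouts[1])
    return analysis.recruitment_distance_distribution(
        control, antagonist, spec_h, downsample=downsample, seed=seed)


def recruitment_experiment(kernel_mode: str, n_trials: int = 5,
                           seed: int = 0, dt: float = 1.0):
    """Trial-averaged recruitment-distance histogram and its mode.

    Per-trial seeds are seed + trial index (fresh network instance and
    input realization each trial).  Returns (results, histogram, mode):
    the histogram is the mean count per discrete channel distance across
    trials, the mode its argmax.
    """
    results = [gaba_recruitment_trial(kernel_mode, seed + i, dt=dt)
               for i in range(n_trials)]
    hists = [r.distance_histogram() for r in results]
    table = pd.concat(hists, axis=1).fillna(0.0)
    mean_hist = table.mean(axis=1)
    mode = float(mean_hist.idxmax())
    return results, mean_hist, mode


def background_correlation_summary(duration: float = 200_000.0,
                                   seed: int = 0, n_sample: int = 500,
                                   kernel_mode: str = "non_monotonic",
                                   dt: float = 1.0
                                   ) -> analysis.CorrelationSummary:
    """Background-only pairwise correlations on one hemisphere.

    Runs the network without any stimulus for ``duration`` ms and returns
    the Pearson-coefficient summary of 300 ms-filtered spike trains for
    ``n_sample`` randomly chosen neurons.
    """
    kernel = ConnectivityKernel.default(kernel_mode)
    spec_h = build_hemisphere(ChannelGrid(), kernel, seed=seed)
    spikes = simulate(spec_h, None,
                      SimulationConfig(duration=duration, dt=dt, seed=seed))
    return analysis.pairwise_correlation_histograms(
        spikes, spec_h, n_sample=n_sample, seed=seed, phase="no_stim")
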