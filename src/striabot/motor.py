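"""Spike-to-motor transformation and unicycle trajectory integration.

The designated action channels drive a differential steering law with
contralateral encoding: the right hemisphere's 'turn_left' channel produces
the left action command a_l, the left hemisphere's 'turn_right' channel
produces a_r.  Population rates f^D1, f^D2 (summed over the channel's
neurons, exponentially filtered with tau = 200 ms) enter

    a_l = Sig(S_D1/N_D1 * f_r^D1 - S_D2/N_D2 * f_r^D2)
    a_r = Sig(S_D1/N_D1 * f_l^D1 - S_D2/N_D2 * f_l^D2)

with Sig(x) = 2 / (1 + exp(-4x + 4)), so D1 activity pushes the
corresponding wheel forward ('Go') and D2 activity brakes it ('No-Go').
Linear velocity and rotation are v = (a_l + a_r)/2 (capped below 2 m/s by
the sigmoid range) and theta = a_l - a_r in rad/s (positive = left turn).
The robot itself is an ideal planar unicycle integrated by explicit Euler.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .network import NetworkSpec
from .params import D1, D2, MotorParameters
from .simulate import SpikeData

__all__ = [
    "sigmoid",
    "exp_filter",
    "filtered_population_rate",
    "action_commands",
    "velocity_rotation",
    "integrate_trajectory",
    "run_robot",
]


def sigmoid(x):
    """Sig(x) = 2 / (1 + exp(-4x + 4)): strictly increasing, range (0, 2)."""
    return 2.0 / (1.0 + np.exp(-4.0 * np.asarray(x, dtype=float) + 4.0))


def exp_filter(counts: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Causal exponential filter of a per-step event-count series.

    Kernel (1/tau) exp(-t/tau) (unit area), so the filtered series is in
    events/s when ``dt`` and ``tau`` are in ms: a single event produces a
    peak of 1000/tau s^-1 decaying e-fold every tau.
    """
    counts = np.asarray(counts, dtype=float)
    a = np.exp(-dt / tau)
    gain = 1000.0 / tau
    # one-pole recursion y[i] = a*y[i-1] + gain*c[i]
    return lfilter([gain], [1.0, -a], counts, axis=-1)


def filtered_population_rate(spike_times: np.ndarray, duration: float,
                             dt: float, tau: float) -> np.ndarray:
    """Summed filtered rate (spks/s) of a population from its spike times."""
    n_steps = int(round(duration / dt))
    edges = np.arange(n_steps + 1) * dt
    counts, _ = np.histogram(spike_times, bins=edges)
    return exp_filter(counts, dt, tau)


def action_commands(f_r_d1, f_r_d2, f_l_d1, f_l_d2,
                    params: MotorParameters | None = None):
    """Action commands (a_l, a_r) from the four filtered channel rates.

    ``f_r_*`` are the right hemisphere's 'turn_left' channel rates (driving
    a_l), ``f_l_*`` the left hemisphere's 'turn_right' channel rates
    (driving a_r); all summed over the population, in spks/s, >= 0.
    """
    params = params or MotorParameters()
    for f in (f_r_d1, f_r_d2, f_l_d1, f_l_d2):
        if np.any(np.asarray(f) < 0):
            raise ValueError("population rates must be non-negative")
    w1, w2 = params.S_D1 / params.N_D1, params.S_D2 / params.N_D2
    a_l = sigmoid(w1 * np.asarray(f_r_d1) - w2 * np.asarray(f_r_d2))
    a_r = sigmoid(w1 * np.asarray(f_l_d1) - w2 * np.asarray(f_l_d2))
    return a_l, a_r


def velocity_rotation(a_l, a_r):
    """(v, theta) from action commands: v = (a_l+a_r)/2, theta = a_l-a_r."""
    a_l, a_r = np.asarray(a_l, dtype=float), np.asarray(a_r, dtype=float)
    if np.any((a_l < 0) | (a_l > 2)) or np.any((a_r < 0) | (a_r > 2)):
        raise ValueError("action commands must lie in [0, 2]")
    return (a_l + a_r) / 2.0, a_l - a_r


def integrate_trajectory(v: np.ndarray, theta: np.ndarray,
                         dt: float) -> pd.DataFrame:
    """Explicit-Euler unicycle kinematics from (v, theta) command series.

    ``dt`` in ms; v in m/s, theta in rad/s.  Columns: t_ms, v, theta, x, y,
    heading.  Pose at row i is the pose *after* applying command i.
    """
    v = np.asarray(v, dtype=float)
    theta = np.asarray(theta, dtype=float)
    dt_s = dt / 1000.0
    heading = np.cumsum(theta) * dt_s
    # position uses the heading at the start of each step
    head_prev = np.concatenate([[0.0], heading[:-1]])
    x = np.cumsum(v * np.cos(head_prev)) * dt_s
    y = np.cumsum(v * np.sin(head_prev)) * dt_s
    t = (np.arange(len(v)) + 1) * dt
    return pd.DataFrame({"t_ms": t, "v": v, "theta": theta,
                         "x": x, "y": y, "heading": heading})


def run_robot(spikes: SpikeData, spec: NetworkSpec,
              params: MotorParameters | None = None,
              dt: float = 1.0) -> pd.DataFrame:
    """Full readout: spikes -> action commands -> trajectory.

    Returns a trace with columns t_ms, a_l, a_r, v, theta, x, y, heading,
    sampled at the simulation step.
    """
    params = params or MotorParameters()
    ac = spec.action_channels

    def channel_rate(hemi: str, channel: str, ct: str) -> np.ndarray:
        ids = spec.ids(hemisphere=hemi, cell_type=ct,
                       channels=[ac[channel]])
        sel = spikes.select(ids)
        return filtered_population_rate(sel.times, spikes.duration, dt,
                                        params.tau_motor)

    f_r_d1 = channel_rate("R", "turn_left", D1)
    f_r_d2 = channel_rate("R", "turn_left", D2)
    f_l_d1 = channel_rate("L", "turn_right", D1)
    f_l_d2 = channel_rate("L", "turn_right", D2)

    a_l, a_r = action_commands(f_r_d1, f_r_d2, f_l_d1, f_l_d2, params)
    v, theta = velocity_rotation(a_l, a_r)
    traj = integrate_trajectory(v, theta, dt)
    traj.insert(1, "a_l", a_l)
    traj.insert(2, "a_r", a_r)
    return traj


def path_length(traj: pd.DataFrame, t_start: float = 0.0,
                t_stop: float | None = None) -> float:
    """Arc length (m) of the trajectory within [t_start, t_stop] ms."""
    m = traj["t_ms"] >= t_start
    if t_stop is not None:
        m &= traj["t_ms"] <= t_stop
    sub = traj.loc[m]
    dx = np.diff(sub["x"].to_numpy())
    dy = np.diff(sub["y"].to_numpy())
    return float(np.hypot(dx, dy).sum())


def net_heading_change(traj: pd.DataFrame, t_start: float = 0.0,
                       t_stop: float | None = None) -> float:
    """Heading change (rad) accumulated within [t_start, t_stop] ms."""
    m = traj["t_ms"] >= t_start
    if t_stop is not None:
        m &= traj["t_ms"] <= t_stop
    sub = traj.loc[m, "heading"].to_numpy()
    return float(sub[-1] - sub[0])
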