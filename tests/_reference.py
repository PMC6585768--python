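"""Shared test helpers: DC protocols and an independent reference integrator."""

import numpy as np

from striabot.params import BackgroundDrive, D1, D2, NEURON_PARAMS
from striabot.protocols import StimulusBlock, StimulusProtocol


def dc_protocol(amplitudes, duration=5000.0):
    """DC blocks per cell type applied to the whole network, whole run."""
    blocks = [StimulusBlock(hemisphere="both", cell_type=ct, kind="dc",
                            t_start=0.0, t_stop=duration, amplitude_pA=amp)
              for ct, amp in amplitudes.items()]
    return StimulusProtocol(name="toy_dc", duration=duration,
                            blocks=tuple(blocks))


def silence_background(spec):
    spec = spec.copy()
    spec.background = {D1: BackgroundDrive(0.0), D2: BackgroundDrive(0.0)}
    return spec


def feedforward_only(spec):
    """Keep only D1 -> D2 synapses (removes all feedback loops)."""
    spec = spec.copy()
    neurons = spec.neurons.set_index("id")
    ff = ((neurons["type"].loc[spec.pre].to_numpy() == D1)
          & (neurons["type"].loc[spec.post].to_numpy() == D2))
    spec.pre, spec.post = spec.pre[ff], spec.post[ff]
    spec.weight, spec.delay = spec.weight[ff], spec.delay[ff]
    return spec


def reference_integrator(spec, amplitudes, duration, dt=0.01):
    """Independent brute-force forward-Euler integrator at fine dt.

    Straightforward per-step loop over the explicit synapse list with an
    event queue for delayed inhibitory arrivals; deliberately written
    differently from the production integrator.
    """
    neurons = spec.neurons
    n = len(neurons)
    types = neurons["type"].to_numpy()
    P = {ct: NEURON_PARAMS[ct] for ct in (D1, D2)}
    get = lambda attr: np.array([getattr(P[t], attr) for t in types])
    V_rest, V_th = get("V_rest"), get("V_thresh")
    V_reset, g_L, C_m = get("V_reset"), get("g_L"), get("C_m")
    E_ex, E_in = get("E_ex"), get("E_in")
    tau_ex, tau_in = get("tau_syn_ex"), get("tau_syn_in")
    t_ref = get("t_ref")
    I = np.array([amplitudes[t] for t in types])

    targets = {i: [] for i in range(n)}
    for pre, post, w, d in zip(spec.pre, spec.post, spec.weight, spec.delay):
        targets[int(pre)].append((int(post), w, d))

    n_steps = int(round(duration / dt))
    V = V_rest.copy()
    g_ex = np.zeros(n)
    g_in = np.zeros(n)
    ref_until = np.full(n, -1.0)
    pending = {}
    counts = np.zeros(n, dtype=int)
    for s in range(n_steps):
        t = s * dt
        for post, w in pending.pop(s, []):
            g_in[post] += w
        dV = (-g_L * (V - V_rest) - g_ex * (V - E_ex)
              - g_in * (V - E_in) + I) / C_m
        active = t >= ref_until
        V = np.where(active, V + dt * dV, V_reset)
        spikers = np.nonzero(active & (V >= V_th))[0]
        if len(spikers):
            V[spikers] = V_reset[spikers]
            ref_until[spikers] = t + t_ref[spikers]
            counts[spikers] += 1
            for i in spikers:
                for post, w, d in targets[i]:
                    arrival = s + int(round(d / dt))
                    pending.setdefault(arrival, []).append((post, w))
        g_ex -= dt * g_ex / tau_ex
        g_in -= dt * g_in / tau_in
    return counts
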