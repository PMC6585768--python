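# Model and methods

## The network

The model is a two-hemisphere spiking network of striatal medium spiny
neurons (MSNs).  Each hemisphere consists of 36 *channels* — functional
units of 40 D1- and 40 D2-MSNs each — arranged on a 6x6 grid with wrapped
edges (a torus, so no channel is privileged by boundary effects).  A channel
stands for one candidate action; two adjacent channels per hemisphere,
`turn_left` at (2, 2) and `turn_right` at (2, 3), are wired to a simulated
robot with contralateral encoding (the right hemisphere's `turn_left`
channel drives the left-turn command).

Neurons are leaky integrate-and-fire units with conductance-based synapses:

    C_m dV/dt = -g_L (V - V_rest) - g_ex (V - E_ex) - g_in (V - E_in) + I_ext

with exponentially decaying conductances (tau_syn_ex = 5 ms,
tau_syn_in = 10 ms).  Published membrane constants differ between the types
(D1: V_rest = -87.2 mV, C_m = 195 pF, g_L = 9 nS; D2: -85.4 mV, 159 pF,
4.5 nS; threshold -50 mV for both), making D2 cells the more excitable
(rheobase 159.3 pA vs 334.8 pA).  The remaining constants are the standard
conductance-LIF completions used by mainstream spiking simulators, and are
configurable: E_ex = 0 mV, E_in = -85 mV, V_reset = -60 mV, t_ref = 2 ms.
We note that an alternative completion with E_in = -74 mV places the
inhibitory reversal above the network's operating point at rest, weakening
the lateral inhibition that the whole architecture is built around; we do
not use it.

All MSN->MSN synapses are GABAergic.  Base pairwise connection
probabilities are type-specific (D1->D1 0.07, D2->D1 0.13, D1->D2 0.05,
D2->D2 0.23) and are scaled by a distance-dependent kernel over channel
categories: x1.2 within a channel, x3.4 for the 8 surrounding channels
("near"), x0.3 beyond.  This *non-monotonic* profile — connectivity peaking
at ~40 um rather than at zero distance — is the structural hypothesis under
test; the *monotonic* control swaps the within/near factors (3.4/1.2).
"Near" defaults to the 8-neighborhood (wrapped Euclidean distance <=
sqrt(2)) for consistency with the Euclidean distance categories used in the
correlation analysis; a 4-neighborhood is available as configuration.
Conductance magnitudes are fixed per type pair (|J|: 0.75, 1.7, 0.85,
1.35 nS; the table's negative signs are read as an inhibitory routing flag,
not a negative conductance) and delays grow with distance (1.0 / 2.5 /
4.5 ms).  Connections are sampled independently per ordered pair — directed,
no autapses, no multapses — and both hemispheres are built from independent
seed streams with no interhemispheric synapses.

## Background drive

Every neuron receives independent excitatory Poisson input at 2.5 nS per
event.  The published drive is stated as a per-generator rate (80 spks/s
for D1, 57 spks/s for D2); a single such train cannot bring an MSN within
fluctuation range of threshold (isolated-cell rates < 0.001 spks/s at any
integration step), so the model completes the background as a small pool of
`n_sources` independent trains per neuron at those per-train rates.  The
pool size is the one free background constant.  It was calibrated once, by
screening n_sources in 3..6 against the qualitative operating regime the
model is designed for: baseline rates in the sub-Hz-to-few-Hz in-vivo MSN
range with the D1 population below the D2 population, few silent cells, and
a motor readout resting well below the sigmoid midpoint so that the
stimulation paradigms modulate behavior in both directions.  n_sources = 4
is the unique value satisfying all of these (baseline ~0.4 spks/s D1,
~1.2 spks/s D2); 3 leaves half the D1 population silent, 5 saturates the
motor readout at rest (and with it the turning behaviors), 6 additionally
erases the D1 < D2 rate ordering.

## Integration

Exponential-Euler at dt = 1 ms (configurable): conductances decay by their
exact exponential factor each step, and the membrane relaxes exactly toward
the fixed point defined by the frozen conductances.  Per step: deliver the
conductance increments due (delayed recurrent inhibition, background and
stimulus excitation), update the membrane, detect end-of-step threshold
crossings (no interpolation), then decay.  Spiking neurons are reset and
clamped for the refractory period while their synaptic inputs keep
integrating.  Delays are rounded to integer step multiples (minimum one
step).  The test suite checks the integrator against an independently
written forward-Euler reference at dt = 0.01 ms on a two-channel network:
counts agree within one spike per neuron over seconds in feedback-free
configurations.  With feedback loops the network is chaotic and
trajectory-level agreement between schemes is not a meaningful target; a
dt-refinement test bounds the population-rate drift instead (< 5% when
halving dt).

## Stimulation paradigms

Global paradigms inject DC current into whole populations from 5 s to 15 s
of a 20 s run: bilateral D1 +115 pA, bilateral D2 +160 pA, unilateral
(left-hemisphere) D1 -175 pA, D2 -100 pA, D1+D2 combined inhibition, D1
+125 pA, D2 +110 pA.  Channel paradigms deliver excitatory Poisson trains
(2.5 nS events — the stimulus synapse weight is unstated in the source
design and reuses the background weight; configurable) to the action
channels: `sequences_D1/D2/D1D2` drive the left `turn_right` channel for
5 s (from t = 5 s) and then the right `turn_left` channel for 5 s at
300 / 120 / 300+150 spks/s; `competing_actions` drives both action channels
of both hemispheres at 250 (D1) and 200 (D2) spks/s from 2 s to 18 s.  The
phase onsets of the sequence paradigms are a package choice (the source
design fixes only the 5 s phase lengths); aligning the first phase with the
5 s onset of the global paradigms keeps the pre-stimulus baseline windows
comparable.

The GABA-antagonist experiment runs a single hemisphere (a slice
preparation) at 25% background with two identical 140 pA / 200 ms pulses to
every neuron, at 5 s (control) and 15 s (antagonist).  All inhibitory
weights are scaled to 20% from t = 10 s — the midpoint between pulses — so
the second pulse alone sees the reduced inhibition.  140 pA is subthreshold
for both types (D2 rheobase 159.3 pA), so recruitment is fluctuation-driven
and shaped by lateral inhibition, which is the point of the assay.

## Motor readout and robot

Per designated channel and cell type the spike trains are summed and
convolved with a unit-area exponential kernel (tau = 200 ms), giving a
population rate f in spks/s.  Action commands are

    a_l = Sig(S_D1/N_D1 * f_r^D1 - S_D2/N_D2 * f_r^D2),   Sig(x) = 2 / (1 + e^(-4x+4))

(a_r symmetric from the left hemisphere), with S_D1 = 2.0, S_D2 = 0.4,
N = 40: D1 activity drives the action ("Go"), D2 activity brakes it
("No-Go"), and the sigmoid bounds commands to (0, 2).  Velocity and
rotation are v = (a_l + a_r)/2 < 2 m/s and theta = a_l - a_r in (-2, 2)
rad/s (inside [-pi, pi]; positive = left turn).  The robot is an ideal
planar unicycle (heading' = theta, x' = v cos heading, y' = v sin heading)
integrated by explicit Euler at the simulation step — a deliberate
replacement of a physics-engine platform, adequate because all behavioral
claims are direction- and magnitude-level.  Motors are driven by the
designated channels only; in `competing_actions` the non-designated
channel of each hemisphere does not reach the motors.

## Analyses

* Rates: 200 ms binning per channel x type or hemisphere x type, in spks/s
  per neuron.
* Pairwise correlations: spike trains sampled at 1 ms, convolved with a
  300 ms exponential kernel (the decay time of GCaMP6f calcium
  transients, so the traces emulate calcium imaging), Pearson-correlated
  over the analysis window with 500 ms excluded after stimulus onset and
  before offset (the exclusion margin is configurable; the source design
  states the exclusion but not its width).  500 neurons are sampled per
  hemisphere; all unordered distinct pairs (124,750) are used — an
  ordered-pair count would double this, and Pearson r is symmetric.
  Zero-variance (silent) trains are dropped and counted.  Pairs are
  grouped within / near / far by the wrapped channel distance.  Histogram
  bins are 0.1 wide and centered on multiples of 0.1 so modes land on
  round values; the "positive mode" is the argmax over bins with positive
  centers.
* Correlation matrices: every 5th neuron per channel (deterministic,
  8 per channel), ordered channel-by-channel so block structure is
  visible.
* Instantaneous population correlation: sliding-window Pearson r(t)
  between the filtered D1 and D2 population traces, windows of 0.3x and
  1.2x the stimulation time; the shuffle control redraws each spike time
  uniformly over the recording, preserving per-neuron counts while
  destroying temporal alignment (the source design does not define its
  shuffle).
* Winning channel: within a hemisphere, the action channel with higher
  summed D2 activity in a sliding 250 ms window wins if the relative
  difference exceeds a 5% margin (the no-winner margin is a package
  choice, configurable); an action is *selected* only when both
  hemispheres agree.
* Recruitment distances: the recorded population is down-sampled to 500
  neurons per trial (emulating an imaging field of view); neurons active
  only during the antagonist bout are assigned the wrapped channel
  distance to their nearest control-bout neighbor; histograms are
  averaged over 5 trials (seeds seed+0..4, a fresh network instance per
  trial) and the mode is reported in channel units (1 unit ~ 40 um).

## Problem sizes

Behavioral runs are 20 s with stimulation on [5, 15] s; recruitment uses
5 trials x 20 s on one hemisphere; pairwise-correlation estimates default
to 200 s runs, and the reproduction script uses a 50 s scaled run (the
histogram tightens with duration but its mode location is stable from
~50 s on).  A full-network 20 s run integrates 5,760 neurons and ~2 million
synapses.

## Known limitations

* The background-pool completion cannot simultaneously satisfy the
  low-baseline motor regime and a within-channel co-activation peak at
  0.6: with n_sources = 4 the within-channel D2-D2 correlation histogram
  peaks at ~0.4 and D1-D1 at ~0.1 (sign structure — within-channel
  positive, near-channel negative, far ~ 0 — is robust across all
  settings examined).  Raising the pool to 5 moves the combined peak to
  0.6 but saturates the motor readout at rest and breaks the turning
  behaviors.  The package keeps the behavioral configuration and reports
  the correlation mode it actually computes.
* At baseline the D1-D2 population anticorrelation is present but weak
  (negative on long windows; short-window estimates fluctuate in sign).
* Single-compartment neurons, static synapses, no fast-spiking or
  cholinergic interneurons, uncorrelated background, and a coarse
  three-tier distance kernel on a 6x6 grid; near-channel anticorrelations
  are likely stronger here than in tissue.
* The sensory loop is open: nothing feeds back from the robot's pose into
  the network.
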