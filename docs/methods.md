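# Methods

`bgloop` simulates the basal ganglia–thalamo-cortical circuit as a network of
extended Izhikevich point neurons, with dopamine acting as a control
parameter that switches the balance between the striatal direct and indirect
pathways. This note documents the model, its calibrated parameters, the
numerical choices, and what the scaled-down simulations used in the tests do
and do not demonstrate.

## Single-neuron model

Every cell is a quadratic threshold-firing (Izhikevich-type) neuron in
dimensional form:

    C dv/dt = k (v − vr)(v − vt) − u − w + I_bias + I_syn(t) + I_DA
      du/dt = a (b (v − vr) − u)
      dw/dt = a2 (b2 (v − vr) − w)        (thalamocortical relay cells only)

with the auxiliary reset: when `v` crosses the peak cutoff a spike is
registered, `v → c`, `u → u + d`, and (TC only) `w → w + d2`. Spike times
use the start-of-step timestamp. Two numerical guards bound the state: `v`
is clamped at −100 mV (the bare quadratic grows without bound below rest and
would otherwise catapult the voltage upward after a strong inhibitory
volley), and the TC slow variable `w` is clamped to `[w_min, w_max]`,
standing in for the saturation of low-threshold Ca²⁺ channel
de-inactivation/inactivation. The `w` floor sets the maximal rebound charge
a hyperpolarised relay cell can accumulate; the ceiling lets the tonic
(relay) firing mode coexist with the burst mode.

Eight cell types are parameterised (`src/bgloop/data/neuron_params.yaml`):
cortical regular-spiking (RS) and fast-spiking (FS) cells, D1- and D2-type
medium spiny neurons (MSNs), GPe and GPi pallidal pacemakers, subthalamic
(STN) cells, and thalamocortical (TC) relay cells. Values were seeded from
canonical parameter regimes for each firing class and then calibrated so the
standard single-cell repertoire holds:

* MSNs are silent at rest with hyperpolarised membranes, show a long
  first-spike latency just above rheobase (slow saddle-node passage with the
  amplifying recovery variable, b < 0), and need substantial cortical drive
  to respond.
* GPe and GPi carry an intrinsic bias current (pA-scale pacemaker drive), so
  they fire fast autonomously and their rheobase with respect to injected
  current is negative; GPi is tuned slightly faster than GPe.
* STN cells fire spontaneously at low rate, and a strong hyperpolarising
  pulse is answered by a rebound burst (slow recovery variable with large
  sensitivity) before spontaneous firing resumes. The same slow/high-gain
  recovery makes the STN a subthreshold resonator in the theta–alpha range —
  a property that shaped the network calibration (below).
* TC cells fire a short high-frequency burst at the onset of a depolarising
  step, relax to tonic spiking with adaptation, and respond to release from
  hyperpolarisation below −80 mV with a rebound burst of three or more
  spikes.

Dopamine (level φ ∈ [0, 1]) enters the MSN dynamics through one signed
coupling coefficient (positive for D1, negative for D2):

* D1: the after-spike increment is scaled by `(1 − c·φ)`. This raises the
  slope of the f-I curve with dopamine while leaving the subthreshold phase
  portrait — and therefore the rheobase — exactly unchanged.
* D2: the mirror image, `d` scaled by `(1 − |c|·(1 − φ))`, plus a tonic
  hyperpolarising current proportional to φ. Dopamine depletion (φ → 0)
  therefore leaves the D2 population maximally excitable, the cellular basis
  of indirect-pathway dominance in the parkinsonian state.

The exact functional form of the dopamine terms is a design choice of this
package (the adaptation/current route was selected because it reproduces the
slope-up/rheobase-invariant D1 signature cleanly); the coupling coefficient
is the only exposed knob, so other forms can be substituted.

Phase-plane tools (`phase_portrait`, `bifurcation_scan`) analyse the planar
(v, u) subsystem — for TC cells the second slow variable is folded in at its
fixed point — locating equilibria as the roots of a quadratic and
classifying them by the Jacobian eigenvalues. The saddle-node current found
by the scan agrees with the bisection rheobase up to the finite-trial bias
of the latter (near the saddle-node the first-spike latency diverges).

## Dopamine schedule

φ(t) = φ_tonic plus a phasic component that jumps to φ_phasic at the onset
of a cortical stimulus window and decays exponentially (τ = 500 ms) after it
ends. The exponential is the minimal smooth model for the post-stimulus
fall-off; the constraint φ_tonic + φ_phasic ≤ 1 keeps φ bounded. Both
receptor families see the same φ (the D1/D2 split is kept as a seam).

## Network

Populations: 800 RS + 200 FS cortical cells (the 4:1 excitatory:inhibitory
ratio), 200 D1- and 200 D2-MSNs, and 100 cells each for GPe, GPi, STN and
TC — 1800 neurons. Wiring is a directed random graph: each (pre, post) pair
connects independently with a per-projection probability; weights are
truncated-normal magnitudes signed by the projection; conduction delays are
per-projection means with uniform per-edge jitter. The pathway skeleton:

* cortex: RS↔RS, RS→FS, FS→RS, FS→FS;
* cortico-striatal: RS→D1 and RS→D2, with dopamine-dependent efficacy
  `max(0, 1 + g·(φ − 0.5))`, g > 0 for D1 and g < 0 for D2, neutral at the
  healthy tonic level φ = 0.5;
* MSN collaterals: D1→D1 and D2→D2 lateral inhibition (the known GABAergic
  collaterals; for D2 they are the substrate of the parkinsonian beta
  rhythm, see below);
* direct: D1 ⊣ GPi; indirect: D2 ⊣ GPe ⊣ STN → GPe/GPi; hyperdirect:
  RS → STN; output: GPe ⊣ GPi ⊣ TC; thalamic relay drive: RS → TC.

Synapses are delta-pulse currents: a presynaptic spike adds the edge weight
(pA, for one integration step) to the target at spike time + delay.
Per-neuron intrinsic-drive jitter (`bias_spread`) gives the pacemaker nuclei
a realistic range of intrinsic rates; without it the population spectrum
carries an artificial line at the one common firing frequency. Each neuron
also receives an independent Poisson background (rate and pulse size per
population) standing in for unmodelled afferents, calibrated so each
population attains its basal rate in the resting scenario. Inhibitory pulse
sizes are kept below ~10 mV per event; stronger single events interact
pathologically with the voltage floor (clamp-and-rebound artifacts), so
strong pathways use many weak synapses (higher probability, smaller weight).

All connection probabilities, weights, delays and background rates live in
`src/bgloop/data/network_defaults.yaml`; they are literature-informed where
possible and otherwise calibrated against the scenario signatures.

## Plasticity

Pair-based additive STDP acts on exactly three connection classes — RS→RS,
RS→FS and RS→D1 — with distinct profiles for the intra-cortical and
cortico-striatal synapses (the latter potentiation-dominant, a minimal
reward-learning flavour). Updates are applied in batches every 1 s from the
spikes of that interval; for the additive all-pairs rule this equals online
updating up to the order in which the hard weight bounds clip (documented
approximation; the batch path is verified against a brute-force O(n²)
pair-sum oracle in the tests). Simultaneous pre/post spikes contribute
nothing. Weights are clamped to per-profile bounds against runaway
potentiation, and sign is preserved. Structural plasticity: an edge whose
weight reaches the zero bound is pruned, and with small probability a fresh
edge appears between a uniformly chosen unconnected pair at the minimum
positive weight; every prune/form event is logged with its timestamp.

## The five scenarios

| # | φ_tonic | φ_phasic | stimulus | GPi→TC |
|---|---------|----------|----------|--------|
| 1 | 0.5 | –   | off | intact |
| 2 | 0.5 | 0.5 | on  | intact |
| 3 | 0.5 | 0   | on  | intact |
| 4 | 0.5 | 0.4 | on  | intact |
| 5 | 0   | –   | off | reduced to 12 % |

The stimulus is a 2 s constant-current step to both cortical populations
(FS cells receive 45 % of the RS amplitude — they are far more excitable
per pA) with ±80 % static per-neuron amplitude jitter; a spatially uniform
step phase-locks every RS cell's adaptation cycle and imposes an artificial
population rhythm on the whole circuit. The protocol simulates warm-up +
7 s, analyses the final 7 s, and places the stimulus at [2 s, 4 s] of that
window. The reference protocol is a 10-minute run analysed over the final
7 s with 20 repetitions (fresh random graph per repetition, seeds derived
from one master seed); the tests and the acceptance script run the
scaled-down mode — 3 s warm-up, 5 repetitions — chosen so a full five-
scenario evaluation completes in a few minutes on one CPU. The weight
drift under STDP between 3 s and 15 s warm-up is below a few percent, so
the shortened settling does not change the reported signatures.

The scenario-5 GPi→TC reduction is implemented as random synaptic loss:
each synapse survives with probability equal to the retained fraction
(0.12 by default, selected by sweeping) at full strength, so the expected
total inhibition scales down while the input remains coarse-grained. A
uniform multiplicative reduction of all weights produces the same mean but a
much smoother input, which clamps the relay cells at an intermediate
potential where neither priming nor release is ever sufficient for rebound
bursting.

## Mechanisms behind the scenario signatures

* Resting mode: the cortex runs an adaptation-driven slow oscillation
  (recurrent excitation charging, spike-frequency adaptation discharging)
  in the delta–theta range; MSNs are nearly silent, GPe/GPi pace fast, the
  tonically active GPi clamps the thalamus silent.
* Gate opening (scenario 2): the phasic surge multiplies cortico-striatal
  efficacy onto D1 and weakens D1 adaptation, the overactive D1 population
  suppresses GPi, and the thalamus relays the cortical stimulus. The
  disinhibited GPe expresses a gamma-band rate line; the STN–GPe subnetwork
  measure is the pooled rate of both populations, whose dominant frequency
  sits in that gamma range during stimulation.
* Gate closed (scenario 3): without phasic dopamine D1 stays weak while the
  hyperdirect cortical drive excites STN; GPi activity surges far above
  50 Hz and the thalamus manages at most a brief low-frequency transient.
* Impaired gating (scenario 4): at φ_phasic = 0.4 the D1 surge only
  partially suppresses GPi, and the weak thalamic response stays confined to
  low frequency.
* Parkinsonian rest (scenario 5): at φ = 0 the D2 population is
  disinhibited; its slow adaptation plus lateral collateral inhibition
  (delays smeared over ~2–16 ms, acting like a slow IPSP) generate a
  population rhythm in the beta band, which propagates down the indirect
  pathway (GPe, STN, and GPi all express beta). With the GPi→TC synapses
  additionally lost, relay cells sit at a partially primed potential and the
  beta troughs of the remaining coarse inhibition release synchronous
  rebound bursts of ≥ 3 spikes — tremor-like activity. Either factor alone
  fails: full-strength synapses clamp the thalamus outright, and synaptic
  loss at healthy tonic dopamine yields only sparse asynchronous firing
  (quantified by the TC pairwise-synchrony contrast in the three-arm test).

One deliberate deviation from the ideal target: in this calibration the STN
spectrum itself remains dominated by low-frequency cortical input during
scenario 2 (the STN's rebound machinery makes it a theta-band resonator, so
it preferentially amplifies exactly that component of the hyperdirect
drive); the gamma claim is therefore evaluated at the subnetwork level
(pooled STN–GPe rate), where it is robust.

## Analysis pipeline

* Firing rates: half-open sliding windows, count/T, divided by population
  size (per-neuron Hz; the raw population-summed convention is behind a
  flag). The reporting grid uses T = 50 ms; spectral work uses a 2 ms grid
  so beta/gamma content is below Nyquist.
* Spectra: Hann-windowed short-time estimates (default 1 s segments, 50 %
  overlap, linear detrend), scaled as power-per-bin so the non-DC bins sum
  to the series variance (Parseval). The power histogram is the time
  average; the dominant frequency is its argmax excluding DC; bands are
  half-open (theta 4–8, alpha 8–13, beta 13–30, gamma 30–150 Hz; 13 Hz is
  beta, 30 Hz gamma). A flat series has no dominant frequency.
* Aggregation across repetitions: ongoing-rhythm measures take the median
  of per-repetition dominant frequencies (the argmax of a run-averaged
  spectrum is biased toward stimulus-locked components); stimulus-response
  measures (the thalamic response in scenarios 3/4) average the rate series
  across repetitions first — an event-related average in which the locked
  response survives and incoherent noise cancels. A window in which the
  population fires below 0.05 Hz is reported as "no rhythmic response" (0).
* Synchrony: mean pairwise Pearson correlation of binned spike counts
  (10 ms bins) across neurons pooled over the listed populations, clipped
  to [0, 1]; silent populations yield NaN (undefined), never a silent 0.
* Rebound bursts: runs of ≥ 3 spikes with inter-spike intervals ≤ 12 ms
  preceded by ≥ 30 ms of silence.
* Directed coupling: least-squares VAR fit (statsmodels) on the
  multivariate rate series; partial directed coherence and its generalised
  form are computed from the fitted coefficient matrices, column-normalised
  per definition. Spike sorting is a no-op in this pipeline: the simulator
  produces labelled spikes, so no principal-component sorting step is
  needed.

## What the scaled-down runs show — and what they do not

The synthetic protocol demonstrates that the model reproduces the
qualitative frequency-band and gating signatures of the five conditions
with fresh random networks at every repetition, within a few minutes of
compute. It does not demonstrate: quantitative match to any specific
electrophysiological recording (all network weights are calibrated, not
fitted); long-horizon STDP phenomena (the 10-minute protocol is available
but not exercised by default); or robustness of the STN-level gamma claim
(see the deviation noted above). Band memberships are robust to the master
seed; individual-run dominant frequencies fluctuate, which is why the
ensemble median/average protocol is part of the method.

## Known limitations

* Delta-pulse synapses have no kinetics; an effective slow-IPSP for the D2
  collaterals is emulated with delay jitter rather than a conductance
  kernel.
* Striatal fast-spiking interneurons, thalamic reticular/interneurons, and
  the thalamo-cortical return loop are not modelled; the FS influence on
  MSNs is folded into the MSN parameters and the dopamine couplings.
* The GPe pause-generating mechanism is synaptically driven only; GPi
  firing in the depleted state runs high (~200 Hz), at the upper edge of
  plausibility, as the price of keeping the gate discrimination sharp.
* Forward Euler at dt = 0.5 ms (network) / 0.1 ms (single-cell) is
  first-order; the dt-refinement test bounds the f-I error at < 5 %.
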