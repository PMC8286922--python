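# bgloop

A spiking-network model of the basal ganglia–thalamo-cortical loop, built
to study how dopamine gates cortical information flow to the thalamus and
how dopamine depletion produces the beta-band oscillations and tremor-like
thalamic activity characteristic of Parkinson's disease.

The package is aimed at computational neuroscientists who want a compact,
fully scriptable circuit model: every nucleus is a population of extended
Izhikevich point neurons, the wiring is a reproducible random graph, and
the analysis pipeline (population firing rates, spectrograms, power
histograms, partial directed coherence, synchrony and burst metrics) is
part of the library.

## The model in brief

Each neuron follows the quadratic threshold-firing equations

```
C v' = k (v − vr)(v − vt) − u − w + I,   u' = a (b (v − vr) − u)
```

with the usual reset at the peak cutoff (v → c, u → u + d); thalamocortical
relay cells carry a second, slower recovery variable `w` whose saturating
de-inactivation produces rebound bursts. The dopamine level φ(t) ∈ [0, 1]
(tonic + stimulus-locked phasic component with exponential decay) has the
classic dual role: it modulates the intrinsic excitability of D1-/D2-type
medium spiny neurons in opposite directions, and it scales the efficacy of
the cortico-striatal synapses up (onto D1) or down (onto D2). The circuit
implements the direct (D1 ⊣ GPi ⊣ thalamus), indirect
(D2 ⊣ GPe ⊣ STN → GPi) and hyperdirect (cortex → STN → GPi) pathways, with
pair-based additive STDP and structural rewiring on the intra-cortical and
cortico-striatal projections.

Five ready-made protocols cover the healthy and parkinsonian regimes:
resting mode, gate-open (phasic dopamine + stimulus), gate-closed (stimulus
without phasic dopamine), impaired gating (attenuated phasic dopamine), and
the dopamine-depleted resting state with weakened GPi→thalamus synapses.
See `docs/methods.md` for the full model description and calibration notes.

## Worked example

Simulate the gate-open scenario at scaled-down warm-up and summarise it:

```
$ bgloop run --scenario 2 --reps 3 --seed 11 --out runs/sc2 --fast
wrote 3 repetitions to runs/sc2
$ bgloop analyze --run-dir runs/sc2 -p GPi -p TC
{
  "GPi": {
    "mean_rate_hz": 158.29952380952383,
    "dominant_frequency_hz": 2.0,
    "band": "delta",
    "band_power_fraction": 0.2806001632640216
  },
  "TC": {
    "mean_rate_hz": 0.39999999999999997,
    "dominant_frequency_hz": 2.0,
    "band": "delta",
    "band_power_fraction": 0.11486127500489626
  }
}
```

The GPi spectrum is dominated by the slow stimulus-locked modulation — its
fast tonic firing collapses while the direct pathway suppresses it during
the 2 s stimulus (the "gate" opening) — and the thalamus, silent in the
resting scenario, fires during the stimulus window (its mean over the full
7 s analysis window stays below 1 Hz). `bgloop report`
renders the corresponding raster + average-rate figures, spectrograms and
power histograms; `bgloop neuron` exposes the single-cell tools (traces,
f-I curves, rheobase, phase planes):

```
$ bgloop neuron rheobase --cell-type GPe --tol 4
-21.4844
```

(a negative rheobase: pallidal cells are autonomous pacemakers).

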