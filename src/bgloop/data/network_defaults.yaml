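# Network construction defaults: population sizes, Poisson background drive,
# per-neuron intrinsic-drive jitter (bias_spread, pA), projection
# probabilities / weight magnitudes (pA pulse) / conduction delays (ms), and
# STDP profiles.  Probabilities and delays are literature-informed; weights
# and drives are calibrated so each population attains its basal rate in the
# resting mode and the five scenario signatures hold (see docs/methods.md).
# version: 2
populations:
  CTX_RS:
    size: 800
    background_rate: 400.0
    background_weight: 350.0
  CTX_FS:
    size: 200
    background_rate: 400.0
    background_weight: 150.0
  D1_MSN:
    size: 200
    background_rate: 550.0
    background_weight: 350.0
  D2_MSN:
    size: 200
    background_rate: 850.0
    background_weight: 350.0
  GPe:
    size: 100
    background_rate: 100.0
    background_weight: 100.0
    bias_spread: 8.0
  GPi:
    size: 100
    background_rate: 300.0
    background_weight: 150.0
    bias_spread: 25.0
  STN:
    size: 100
    background_rate: 100.0
    background_weight: 100.0
    bias_spread: 8.0
  TC:
    size: 100
    background_rate: 300.0
    background_weight: 250.0
stdp_profiles:
  intracortical:
    potentiation_amplitude: 0.5
    depression_amplitude: 0.55
    potentiation_tau: 17.0
    depression_tau: 34.0
    weight_bounds:
    - 0.0
    - 600.0
    allow_rewiring: true
    rewire_probability: 0.05
    min_positive_weight: 1.0
  corticostriatal:
    potentiation_amplitude: 0.8
    depression_amplitude: 0.6
    potentiation_tau: 20.0
    depression_tau: 20.0
    weight_bounds:
    - 0.0
    - 900.0
    allow_rewiring: true
    rewire_probability: 0.05
    min_positive_weight: 1.0
projections:
- source: CTX_RS
  target: CTX_RS
  sign: excitatory
  p: 0.05
  weight_mean: 320.0
  weight_spread: 50.0
  delay: 1.5
  delay_jitter: 0.5
  plastic: true
  stdp_profile: intracortical
- source: CTX_RS
  target: CTX_FS
  sign: excitatory
  p: 0.05
  weight_mean: 250.0
  weight_spread: 50.0
  delay: 1.0
  delay_jitter: 0.5
  plastic: true
  stdp_profile: intracortical
- source: CTX_FS
  target: CTX_RS
  sign: inhibitory
  p: 0.1
  weight_mean: 250.0
  weight_spread: 60.0
  delay: 1.0
  delay_jitter: 0.5
- source: CTX_FS
  target: CTX_FS
  sign: inhibitory
  p: 0.1
  weight_mean: 300.0
  weight_spread: 60.0
  delay: 1.0
  delay_jitter: 0.5
- source: CTX_RS
  target: D1_MSN
  sign: excitatory
  p: 0.05
  weight_mean: 600.0
  weight_spread: 120.0
  delay: 5.0
  delay_jitter: 1.0
  plastic: true
  stdp_profile: corticostriatal
  da_gain: 2.4
- source: CTX_RS
  target: D2_MSN
  sign: excitatory
  p: 0.05
  weight_mean: 650.0
  weight_spread: 120.0
  delay: 5.0
  delay_jitter: 1.0
  da_gain: -1.6
- source: D2_MSN
  target: D2_MSN
  sign: inhibitory
  p: 0.15
  weight_mean: 400.0
  weight_spread: 60.0
  delay: 12.0
  delay_jitter: 7.0
- source: D1_MSN
  target: D1_MSN
  sign: inhibitory
  p: 0.1
  weight_mean: 300.0
  weight_spread: 60.0
  delay: 1.5
  delay_jitter: 0.5
- source: CTX_RS
  target: STN
  sign: excitatory
  p: 0.05
  weight_mean: 450.0
  weight_spread: 180.0
  delay: 2.5
  delay_jitter: 0.5
- source: CTX_RS
  target: TC
  sign: excitatory
  p: 0.03
  weight_mean: 600.0
  weight_spread: 160.0
  delay: 8.0
  delay_jitter: 1.0
- source: D1_MSN
  target: GPi
  sign: inhibitory
  p: 0.25
  weight_mean: 60.0
  weight_spread: 20.0
  delay: 7.0
  delay_jitter: 1.0
- source: D2_MSN
  target: GPe
  sign: inhibitory
  p: 0.2
  weight_mean: 250.0
  weight_spread: 70.0
  delay: 7.0
  delay_jitter: 1.0
- source: GPe
  target: STN
  sign: inhibitory
  p: 0.1
  weight_mean: 350.0
  weight_spread: 70.0
  delay: 3.0
  delay_jitter: 1.0
- source: GPe
  target: GPi
  sign: inhibitory
  p: 0.1
  weight_mean: 150.0
  weight_spread: 50.0
  delay: 3.0
  delay_jitter: 0.5
- source: GPe
  target: GPe
  sign: inhibitory
  p: 0.05
  weight_mean: 100.0
  weight_spread: 20.0
  delay: 1.0
  delay_jitter: 0.5
- source: STN
  target: GPe
  sign: excitatory
  p: 0.1
  weight_mean: 100.0
  weight_spread: 50.0
  delay: 3.0
  delay_jitter: 1.0
- source: STN
  target: GPi
  sign: excitatory
  p: 0.2
  weight_mean: 400.0
  weight_spread: 80.0
  delay: 3.0
  delay_jitter: 0.5
- source: GPi
  target: TC
  sign: inhibitory
  p: 0.15
  weight_mean: 650.0
  weight_spread: 130.0
  delay: 5.0
  delay_jitter: 1.0
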