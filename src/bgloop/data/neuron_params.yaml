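# Per-cell-type parameters of the extended quadratic threshold-firing model.
#   C dv/dt = k (v-vr)(v-vt) - u - w + bias + I ;  du/dt = a (b (v-vr) - u)
# Units: capacitance pF, potentials mV, recovery_gain 1/ms,
# recovery_sensitivity pA/mV, after_spike_increment pA,
# quadratic_gain pA/mV^2, bias_current pA.  slow2_params (TC only) add the
# saturating rebound variable w.  Values are calibrated defaults reproducing
# each population's qualitative single-cell repertoire (see docs/methods.md).
# version: 2
D1_MSN:
  membrane_capacitance: 50.0
  resting_potential: -80.0
  threshold_potential: -37.0
  peak_cutoff: 40.0
  reset_potential: -55.0
  recovery_gain: 0.01
  recovery_sensitivity: -20.0
  after_spike_increment: 150.0
  quadratic_gain: 1.0
  bias_current: 0.0
  da_coupling: 0.9
D2_MSN:
  membrane_capacitance: 50.0
  resting_potential: -80.0
  threshold_potential: -37.0
  peak_cutoff: 40.0
  reset_potential: -55.0
  recovery_gain: 0.012
  recovery_sensitivity: -20.0
  after_spike_increment: 150.0
  quadratic_gain: 1.0
  bias_current: 0.0
  da_coupling: -0.5
  da_current_scale: 220.0
GPe:
  membrane_capacitance: 20.0
  resting_potential: -55.0
  threshold_potential: -40.0
  peak_cutoff: 25.0
  reset_potential: -47.0
  recovery_gain: 0.2
  recovery_sensitivity: 0.3
  after_spike_increment: 60.0
  quadratic_gain: 1.0
  bias_current: 80.0
GPi:
  membrane_capacitance: 20.0
  resting_potential: -55.0
  threshold_potential: -40.0
  peak_cutoff: 25.0
  reset_potential: -47.0
  recovery_gain: 0.2
  recovery_sensitivity: 0.3
  after_spike_increment: 60.0
  quadratic_gain: 1.0
  bias_current: 170.0
STN:
  membrane_capacitance: 50.0
  resting_potential: -60.0
  threshold_potential: -45.0
  peak_cutoff: 30.0
  reset_potential: -52.0
  recovery_gain: 0.01
  recovery_sensitivity: 8.0
  after_spike_increment: 60.0
  quadratic_gain: 0.7
  bias_current: 165.0
CTX_RS:
  membrane_capacitance: 100.0
  resting_potential: -60.0
  threshold_potential: -40.0
  peak_cutoff: 35.0
  reset_potential: -50.0
  recovery_gain: 0.004
  recovery_sensitivity: -2.0
  after_spike_increment: 150.0
  quadratic_gain: 0.7
  bias_current: 0.0
CTX_FS:
  membrane_capacitance: 20.0
  resting_potential: -55.0
  threshold_potential: -40.0
  peak_cutoff: 25.0
  reset_potential: -45.0
  recovery_gain: 0.2
  recovery_sensitivity: 0.5
  after_spike_increment: 40.0
  quadratic_gain: 1.0
  bias_current: 0.0
TC:
  membrane_capacitance: 30.0
  resting_potential: -60.0
  threshold_potential: -45.0
  peak_cutoff: 35.0
  reset_potential: -48.0
  recovery_gain: 0.02
  recovery_sensitivity: 0.5
  after_spike_increment: 6.0
  quadratic_gain: 0.35
  bias_current: 35.0
  slow2_params:
    recovery_gain: 0.005
    recovery_sensitivity: 20.0
    after_spike_increment: 1.0
    w_min: -90.0
    w_max: 100.0
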