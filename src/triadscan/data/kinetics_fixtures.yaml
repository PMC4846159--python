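# Calibrated kinetics fixture presets for the 12-entry activity panel.
#
# Each entry fixes the designed normalized fold activity of a construct and the
# shape parameters of its synthetic absorbance trace.  Steady-state rates are
# NOT stored: the generator solves for the steady rate that makes the analysis
# pipeline (reference subtraction, Beer-Lambert conversion, ordinary
# least-squares initial rate over the documented window, normalization by the
# no-peptide control) recover exactly the designed fold on a noiseless trace.
#
# Folds 7.7 (assembled fusion, id 2), 1.9 (free monomer, id 3) and
# 0.24 x 7.7 (leupeptin-inhibited assembly, id 12) are the experimentally
# reported panel values; the remaining mutants carry qualitative folds that
# encode "S1, S6, H10 and the C-terminus are essential" without asserting
# unpublished numbers.  Burst amplitudes scale with activity for assembled
# constructs; non-assembled constructs (ids 3, 4) show no burst.  Assembled
# constructs carry a turbidity ramp (cloudy suspensions) that the matched
# reference channel removes.
defaults:
  background_rate_M_s: 2.0e-8     # uncatalyzed p-NPA hydrolysis in PBS/MeOH
  noise_sigma_AU: 5.0e-4          # photometer noise per channel
  duration_s: 1800.0
  dt_s: 5.0
  rate_window_s: 120.0
  endpoint_s: 1200.0
  epsilon_M_cm: 15600.0
  pathlength_cm: 1.0

control:
  panel_id: 1
  label: standard
  designed_fold: 1.0
  burst_amplitude_M: 0.0
  burst_rate_per_s: 0.0
  turbidity_ramp_AU_s: 0.0
  method: initial-rate

fixtures:
  - {panel_id: 2,  label: CP4-AB,           designed_fold: 7.7,   burst_amplitude_M: 2.0e-6,  burst_rate_per_s: 0.03, turbidity_ramp_AU_s: 5.0e-5, method: initial-rate}
  - {panel_id: 3,  label: CP4,              designed_fold: 1.9,   burst_amplitude_M: 0.0,     burst_rate_per_s: 0.0,  turbidity_ramp_AU_s: 0.0,    method: initial-rate}
  - {panel_id: 4,  label: CP4-GPP10,        designed_fold: 1.8,   burst_amplitude_M: 0.0,     burst_rate_per_s: 0.0,  turbidity_ramp_AU_s: 1.0e-5, method: endpoint-1200s}
  - {panel_id: 5,  label: CP4-AB-E3A,       designed_fold: 6.5,   burst_amplitude_M: 1.7e-6,  burst_rate_per_s: 0.03, turbidity_ramp_AU_s: 5.0e-5, method: initial-rate}
  - {panel_id: 6,  label: CP4-AB-amide,     designed_fold: 2.5,   burst_amplitude_M: 6.5e-7,  burst_rate_per_s: 0.03, turbidity_ramp_AU_s: 5.0e-5, method: initial-rate}
  - {panel_id: 7,  label: CP4-AB-S1A,       designed_fold: 4.5,   burst_amplitude_M: 1.2e-6,  burst_rate_per_s: 0.03, turbidity_ramp_AU_s: 5.0e-5, method: initial-rate}
  - {panel_id: 8,  label: CP4-AB-S4A,       designed_fold: 7.0,   burst_amplitude_M: 1.8e-6,  burst_rate_per_s: 0.03, turbidity_ramp_AU_s: 5.0e-5, method: initial-rate}
  - {panel_id: 9,  label: CP4-AB-S6A,       designed_fold: 4.0,   burst_amplitude_M: 1.0e-6,  burst_rate_per_s: 0.03, turbidity_ramp_AU_s: 5.0e-5, method: initial-rate}
  - {panel_id: 10, label: CP4-AB-H9A,       designed_fold: 6.8,   burst_amplitude_M: 1.8e-6,  burst_rate_per_s: 0.03, turbidity_ramp_AU_s: 5.0e-5, method: initial-rate}
  - {panel_id: 11, label: CP4-AB-H10A,      designed_fold: 2.2,   burst_amplitude_M: 5.7e-7,  burst_rate_per_s: 0.03, turbidity_ramp_AU_s: 5.0e-5, method: initial-rate}
  - {panel_id: 12, label: CP4-AB-leupeptin, designed_fold: 1.848, burst_amplitude_M: 4.8e-7,  burst_rate_per_s: 0.03, turbidity_ramp_AU_s: 5.0e-5, method: initial-rate}
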