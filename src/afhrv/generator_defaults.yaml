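# Calibrated defaults of the synthetic tachogram generator (see docs/methods.md).
# Calibration contract checked by scripts/calibrate.py; bump `version` when
# any value changes.
version: 1
sr:
  mean_rr: 858.0        # ms, typical sinus-rhythm mean in long-term Holter AF cohorts
  ar_coefficient: 0.95  # AR(1) memory of the slow autonomic drift
  innovation_sd: 6.0    # ms
  rsa_amplitude: 10.0   # ms, respiratory sinus arrhythmia
  rsa_period: 6.0       # s  (~0.17 Hz resting breathing)
  grid: 0.0078125       # s, 1/128 (Holter sampling grid)
af:
  mean_rr: 698.0        # ms
  sd: 110.0             # ms, near-random ventricular response
  correlation: 0.0      # i.i.d.
  grid: 0.0078125
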