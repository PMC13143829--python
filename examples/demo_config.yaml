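# Small end-to-end demonstration configuration: a correlated-flow speckle
# movie, an expanding spheroid mask series and a 60-patient cohort, sized to
# run in well under a minute on one CPU.
seed: 7
piv:
  chunk_length: 10
generate:
  movie:
    kind: correlated
    xi_true_px: 40.0
    vrms: 2.0
    shape: [320, 320]
    n_frames: 11
  wetting:
    r0_um: 100.0
    radial_speed_um_per_h: 10.0
    t_max_h: 48.0
    dt_h: 4.0
  cohort:
    n_patients: 60
    hazard_ratio: 3.0
    fraction_below_threshold: 0.05
    censoring_rate: 0.3
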