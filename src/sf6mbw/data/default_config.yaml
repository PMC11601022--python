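dead_space_ml: 4.6
tracer_fraction: 0.04
end_of_test_ratio: 0.025
end_of_test_consensus: false
min_breath_volume_ml: 2.0
min_breath_duration_s: 0.3
flow_hysteresis_fraction: 0.02
end_tidal_window_fraction: 0.05
phase_jump_k: 5.0
phase_jump_min_gmol: 0.15
washin_plateau_breaths: 5
washin_plateau_tolerance: 0.005
respirogram_bin_ml: 1.0
boundary_breaths: 5
boundary_min_separation_gmol: 0.05
tcc_overrange_breath_fraction: 0.1
side_chamber_correction: true
side_chamber_scaling: affine
extraction_denominator_min: 0.05
clamp_ceiling_factor: 1.25
volume_mode: atp
sensor_temperature_k: null
subtract_dead_space_from_cev: true
qc_clamped_fraction_max: 0.05
qc_breath_volume_cv_max: 0.4
qc_outcome_deviation_fraction: 0.25
qc_min_accepted_trials: 2
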