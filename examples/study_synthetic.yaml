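# Example study configuration with SYNTHETIC empirical anchors.
#
# The empirical_diffs below are illustrative placeholder values shaped like
# a dual-task dissociation (dual task at test disrupts standard AGL, dual
# task anywhere disrupts transfer AGL); they are NOT measurements.  Replace
# them with the per-condition mean hits-minus-false-alarms values of the
# behavioral study you want to model, and set endorsement_rate to the
# observed proportion of "grammatical" responses.
#
# Delete the empirical_diffs block entirely to have `hemagl run` generate
# internally consistent anchors by simulating HEM-TC at the reference
# combination given under `anchors:`.

materials:
  n_train: 20
  n_test_per_class: 16
  min_length: 3
  max_length: 8

grid:
  g_values: [2, 3, 4, 5]
  rate_levels: [[0.1, 0.8], [0.2, 0.9], [0.3, 1.0]]

study:
  endorsement_rate: 0.5
  n_participants: 20
  n_iterations: 100
  error_window: 0.02
  empirical_diffs:
    standard:
      single_single: 0.20
      dual_train: 0.18
      dual_test: 0.05
      dual_both: 0.04
    transfer:
      single_single: 0.15
      dual_train: 0.06
      dual_test: 0.06
      dual_both: null   # simulated but not compared
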