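# Default two-arm cohort parameters, calibrated to the published summary
# statistics of the evaluation study: PANAS baseline/post means and SDs per
# arm, and VAS group/time marginal means.  Control-arm change-score SDs and
# the per-arm VAS trajectories are not printed anywhere and are calibration
# choices consistent with the printed marginals (see docs/methods.md).
affect_stress:
  na_baseline_mean: 1.57
  na_baseline_sd: 0.56
  na_change_mean: 0.27
  na_change_sd: 0.61
  pa_baseline_mean: 3.08
  pa_baseline_sd: 0.65
  pa_change_mean: 0.29
  pa_change_sd: 0.61
  item_sd: 0.55
  vas:
    stressed:
      {baseline_mean: 32.92, baseline_sd: 25.0, intermediate_change: 27.08,
       post_change: 1.33, change_sd: 20.0}
    frustrated:
      {baseline_mean: 25.0, baseline_sd: 22.0, intermediate_change: 22.0,
       post_change: 3.0, change_sd: 20.0}
    overstrained:
      {baseline_mean: 22.0, baseline_sd: 22.0, intermediate_change: 24.0,
       post_change: 2.0, change_sd: 20.0}
    ashamed:
      {baseline_mean: 15.0, baseline_sd: 18.0, intermediate_change: 14.0,
       post_change: 4.0, change_sd: 18.0}
affect_control:
  na_baseline_mean: 1.58
  na_baseline_sd: 0.58
  na_change_mean: -0.09
  na_change_sd: 0.61
  pa_baseline_mean: 2.99
  pa_baseline_sd: 0.65
  pa_change_mean: 0.34
  pa_change_sd: 0.61
  item_sd: 0.55
  vas:
    stressed:
      {baseline_mean: 32.92, baseline_sd: 25.0, intermediate_change: 6.28,
       post_change: -6.67, change_sd: 20.0}
    frustrated:
      {baseline_mean: 25.0, baseline_sd: 22.0, intermediate_change: 4.0,
       post_change: -5.0, change_sd: 20.0}
    overstrained:
      {baseline_mean: 22.0, baseline_sd: 22.0, intermediate_change: 5.0,
       post_change: -4.0, change_sd: 20.0}
    ashamed:
      {baseline_mean: 15.0, baseline_sd: 18.0, intermediate_change: 2.0,
       post_change: -2.0, change_sd: 18.0}
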