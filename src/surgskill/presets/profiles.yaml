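# Default skill profiles for the synthetic cohort generator.
#
# Per-segment parameters: submovement count (mean/sd), submovement
# amplitude [cm] and duration [s], fraction of segment time spent idle,
# and planted press counts per hand.  Magnitudes follow the descriptive
# contrasts of the chicken-leg anastomosis study cohort: novices take
# roughly twice as long, travel ~2.5x the path, pause more, tremble
# more, and pinch more often than intermediates.

novice:
  tremor_amp_cm: 0.003
  inter_hand_lag_s: 0.12
  press_width_s: 0.3
  workspace_halfwidth_cm: 1.5
  segments:
    S1: {n_sub_mean: 30, n_sub_sd: 5, amp_mean_cm: 1.2, amp_sd_cm: 0.35,
         dur_mean_s: 0.80, dur_sd_s: 0.15, idle_fraction: 0.40,
         press_left_mean: 20, press_left_sd: 4, press_right_mean: 13, press_right_sd: 4}
    S2: {n_sub_mean: 22, n_sub_sd: 4, amp_mean_cm: 0.85, amp_sd_cm: 0.25,
         dur_mean_s: 0.75, dur_sd_s: 0.15, idle_fraction: 0.38,
         press_left_mean: 9, press_left_sd: 3, press_right_mean: 10, press_right_sd: 3}
    S3: {n_sub_mean: 26, n_sub_sd: 4, amp_mean_cm: 1.5, amp_sd_cm: 0.40,
         dur_mean_s: 0.75, dur_sd_s: 0.15, idle_fraction: 0.42,
         press_left_mean: 6, press_left_sd: 2, press_right_mean: 9, press_right_sd: 3}
    S4: {n_sub_mean: 13, n_sub_sd: 3, amp_mean_cm: 1.7, amp_sd_cm: 0.45,
         dur_mean_s: 0.70, dur_sd_s: 0.15, idle_fraction: 0.28,
         press_left_mean: 5, press_left_sd: 2, press_right_mean: 5, press_right_sd: 2}

intermediate:
  tremor_amp_cm: 0.0015
  inter_hand_lag_s: 0.08
  press_width_s: 0.3
  workspace_halfwidth_cm: 1.5
  segments:
    S1: {n_sub_mean: 12, n_sub_sd: 2, amp_mean_cm: 1.3, amp_sd_cm: 0.30,
         dur_mean_s: 0.80, dur_sd_s: 0.12, idle_fraction: 0.35,
         press_left_mean: 8, press_left_sd: 2, press_right_mean: 6, press_right_sd: 2}
    S2: {n_sub_mean: 9, n_sub_sd: 2, amp_mean_cm: 0.95, amp_sd_cm: 0.25,
         dur_mean_s: 0.70, dur_sd_s: 0.12, idle_fraction: 0.25,
         press_left_mean: 8, press_left_sd: 2, press_right_mean: 4, press_right_sd: 1}
    S3: {n_sub_mean: 10, n_sub_sd: 2, amp_mean_cm: 1.4, amp_sd_cm: 0.35,
         dur_mean_s: 0.70, dur_sd_s: 0.12, idle_fraction: 0.20,
         press_left_mean: 6, press_left_sd: 2, press_right_mean: 4, press_right_sd: 2}
    S4: {n_sub_mean: 6, n_sub_sd: 1, amp_mean_cm: 0.85, amp_sd_cm: 0.25,
         dur_mean_s: 0.65, dur_sd_s: 0.12, idle_fraction: 0.12,
         press_left_mean: 4, press_left_sd: 1, press_right_mean: 4, press_right_sd: 1}
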