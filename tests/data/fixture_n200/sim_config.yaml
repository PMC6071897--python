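base_move_probability: 0.15
deceased_rate: 0.0
demographic_effects: {}
destination_neighboring_mass:
- 0.31
- 0.3400000000000001
- 0.36
- 0.39
- 0.36999999999999994
destination_same_quintile:
- 0.55
- 0.43999999999999995
- 0.37
- 0.33999999999999997
- 0.43000000000000005
encounters_per_window_mean: 2.0
final_encounter_at_endpoint: true
followup_dropout_rate: 0.0
indicator_loading: 1.0
indicator_noise_sd: 0.3
missing_geocode_rate: 0.0
move_probability_by_quintile:
- 0.229
- 0.241
- 0.282
- 0.309
- 0.366
multi_move: false
n_block_groups: 30
n_patients: 200
pediatric_quintile_log_odds: null
po_box_rate: 0.0
quintile_log_odds: null
quintile_shares:
- 0.266
- 0.269
- 0.187
- 0.148
- 0.13
rural_block_group_share: 0.032
seed: 2026
window_months: 14.0
windows:
  baseline_date: '2015-08-31'
  endpoint_date: '2016-10-31'
  enrollment_start: '2014-01-01'
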