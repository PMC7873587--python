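# Regional survey profiles for the five study regions (two in Ethiopia,
# three in Ghana).  Baseline margins, household size and village size are
# the published regional survey characteristics; delta_od/delta_ownership
# default to the conventional-CLTS arm in each region (use
# cltsce.datasets.profile_for(region, arm) for the pilot arms).
#
# Fields without a published value (household-size SD, shared-use and
# unusable-latrine fractions, spending/time means) are realism choices
# documented in docs/methods.md.
Oromia:
  region_name: Oromia
  n_villages: 77
  mean_village_size: 29
  household_size_mean: 6.1
  household_size_sd: 2.2
  baseline_ownership: 0.51
  baseline_od: 0.70
  delta_od: -0.48
  delta_ownership: 0.43
  shared_use_fraction: 0.05
  unusable_fraction: 0.15
  hardware_spend_mean: 1.4
  hired_labor_spend_mean: 0.0
  community_hours_mean: 4.4
SNNP:
  region_name: SNNP
  n_villages: 85
  mean_village_size: 38
  household_size_mean: 5.6
  household_size_sd: 2.0
  baseline_ownership: 0.98
  baseline_od: 0.27
  delta_od: 0.15
  delta_ownership: -0.22
  shared_use_fraction: 0.05
  unusable_fraction: 0.15
  hardware_spend_mean: 0.2
  hired_labor_spend_mean: 0.0
  community_hours_mean: 2.3
Central:
  region_name: Central
  n_villages: 13
  mean_village_size: 116
  household_size_mean: 3.3
  household_size_sd: 1.5
  baseline_ownership: 0.24
  baseline_od: 0.34
  delta_od: -0.06
  delta_ownership: 0.07
  shared_use_fraction: 0.40
  unusable_fraction: 0.20
  hardware_spend_mean: 3.0
  hired_labor_spend_mean: 0.8
  community_hours_mean: 2.0
Upper West:
  region_name: Upper West
  n_villages: 12
  mean_village_size: 68
  household_size_mean: 6.4
  household_size_sd: 2.5
  baseline_ownership: 0.10
  baseline_od: 0.96
  delta_od: -0.13
  delta_ownership: 0.08
  shared_use_fraction: 0.50
  unusable_fraction: 0.20
  hardware_spend_mean: 1.6
  hired_labor_spend_mean: 2.7
  community_hours_mean: 1.8
Volta:
  region_name: Volta
  n_villages: 10
  mean_village_size: 123
  household_size_mean: 3.6
  household_size_sd: 1.5
  baseline_ownership: 0.25
  baseline_od: 0.36
  delta_od: -0.09
  delta_ownership: 0.12
  shared_use_fraction: 0.30
  unusable_fraction: 0.20
  hardware_spend_mean: 6.4
  hired_labor_spend_mean: 3.3
  community_hours_mean: 2.5
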