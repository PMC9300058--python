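# Sedentary colony, southwest Netherlands, North Sea coast.
# See barents.yaml for which values are generating truths vs. simulator choices.
population: northsea
latitude_deg: 51.667
longitude_deg: 4.233
n_cohorts: 5
nests_per_cohort: 8
brood_size_mean: 2.9
n_goslings_target: 116
mean_hatch_doy: 145        # ~25 May
cohort_mean_sd_days: 4.0
hatch_sd_days: 9.0         # breeding much less synchronised than in the Arctic
capture_age_median: 44
capture_age_min: 10
capture_age_max: 86
first_year: 2004
seed: 20040525
traits:
  mass_g:
    adult_A: {male: 2100.0, female: 1900.0}
    hatch_I: 65.0
    true_k: {male: 0.036, female: 0.035}
    true_k_daylight: {male: 0.0020, female: 0.0019}
    sd_cohort: 0.0045
    sd_nest: 0.006
    sd_residual: 80.0
    hatchdate_slope: 5.39
  head_mm:
    adult_A: {male: 95.0, female: 91.0}
    hatch_I: 42.0
    true_k: {male: 0.036, female: 0.035}
    true_k_daylight: {male: 0.0020, female: 0.0020}
    sd_cohort: 0.004
    sd_nest: 0.005
    sd_residual: 2.5
    hatchdate_slope: 0.0
  tarsus_mm:
    adult_A: {male: 78.0, female: 74.0}
    hatch_I: 28.0
    true_k: {male: 0.064, female: 0.059}
    true_k_daylight: {male: 0.0035, female: 0.0031}
    sd_cohort: 0.012
    sd_nest: 0.012
    sd_residual: 2.5
    hatchdate_slope: -0.02
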