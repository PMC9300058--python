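# Short-distance migrant colony, Gotland, Baltic Sea.
# See barents.yaml for which values are generating truths vs. simulator choices.
population: baltic
latitude_deg: 57.417
longitude_deg: 18.883
n_cohorts: 15
nests_per_cohort: 18
brood_size_mean: 3.5
n_goslings_target: 933
mean_hatch_doy: 156        # ~5 June
cohort_mean_sd_days: 3.0
hatch_sd_days: 4.5
capture_age_median: 46
capture_age_min: 28
capture_age_max: 63
first_year: 1986
seed: 19860605
traits:
  mass_g:
    adult_A: {male: 2100.0, female: 1900.0}
    hatch_I: 65.0
    true_k: {male: 0.040, female: 0.042}
    true_k_daylight: {male: 0.0020, female: 0.0021}
    sd_cohort: 0.0045
    sd_nest: 0.006
    sd_residual: 80.0
    hatchdate_slope: -3.91
  head_mm:
    adult_A: {male: 95.0, female: 91.0}
    hatch_I: 42.0
    true_k: {male: 0.037, female: 0.038}
    true_k_daylight: {male: 0.0019, female: 0.0019}
    sd_cohort: 0.004
    sd_nest: 0.005
    sd_residual: 2.5
    hatchdate_slope: -0.08
  tarsus_mm:
    adult_A: {male: 78.0, female: 74.0}
    hatch_I: 28.0
    true_k: {male: 0.078, female: 0.074}
    true_k_daylight: {male: 0.0044, female: 0.0041}
    sd_cohort: 0.012
    sd_nest: 0.012
    sd_residual: 2.5
    hatchdate_slope: -0.05
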