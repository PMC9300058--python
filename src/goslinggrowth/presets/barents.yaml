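# Arctic colony, Kolokolkova Bay, Barents Sea coast.
# Growth coefficients (true_k, true_k_daylight) are per-day / per-daylight-hour
# generating values for the simulator.  A, I, the random-effect SDs, residual
# SDs and hatch-date distribution are plausible field values chosen for the
# simulator, not measured quantities; SDs were calibrated once so that fitted
# fixed-effect standard errors land near the magnitudes seen in colony studies.
population: barents
latitude_deg: 68.583
longitude_deg: 52.333
n_cohorts: 6
nests_per_cohort: 20
brood_size_mean: 3.3
n_goslings_target: 392
mean_hatch_doy: 191        # ~10 July
cohort_mean_sd_days: 2.5
hatch_sd_days: 3.5         # 90% of nests initiated within ~12 days
capture_age_median: 29
capture_age_min: 5
capture_age_max: 42
first_year: 2003
seed: 20030710
traits:
  mass_g:
    adult_A: {male: 2100.0, female: 1900.0}
    hatch_I: 65.0
    true_k: {male: 0.056, female: 0.059}
    true_k_daylight: {male: 0.0023, female: 0.0025}
    sd_cohort: 0.0045
    sd_nest: 0.006
    sd_residual: 80.0
    hatchdate_slope: -8.85
  head_mm:
    adult_A: {male: 95.0, female: 91.0}
    hatch_I: 42.0
    true_k: {male: 0.044, female: 0.045}
    true_k_daylight: {male: 0.0019, female: 0.0019}
    sd_cohort: 0.004
    sd_nest: 0.005
    sd_residual: 2.5
    hatchdate_slope: -0.15
  tarsus_mm:
    adult_A: {male: 78.0, female: 74.0}
    hatch_I: 28.0
    true_k: {male: 0.087, female: 0.089}
    true_k_daylight: {male: 0.0036, female: 0.0037}
    sd_cohort: 0.012
    sd_nest: 0.012
    sd_residual: 2.5
    hatchdate_slope: -0.06
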