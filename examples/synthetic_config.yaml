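# Default synthetic-cohort generator configuration.
# Every key maps to a SyntheticConfig field; omitted keys use the same
# defaults, so an empty file (or no --config) generates this exact cohort.

n_patients: 200          # patients in the cohort
lesions_min: 2           # lesions per patient, uniform on [min, max]
lesions_max: 8
n_features: 40           # radiomic features per lesion
n_archetypes: 3          # latent lesion phenotypes
archetype_scale: 3.0     # SD of archetype centroid coordinates
heterogeneity_mix: 0.5   # P(a lesion draws a non-primary archetype)
n_volume_confounded: 10  # features with a monotone volume dependence
volume_beta: 2.0         # slope on standardized log-volume
noise_sd: 1.0            # within-archetype feature noise
volume_log_mean: 8.0     # lesion volume ~ lognormal (mm^3)
volume_log_sd: 0.8
response_mu: [-50.0, 20.0, -10.0]  # mean percent volume change per archetype
response_sd: 10.0
ctdna_intercept: -0.5
ctdna_beta_heterogeneity: 1.5
ctdna_beta_volume: 0.8
baseline_hazard: 0.35    # events per year
survival_log_hr: 0.7     # on standardized true heterogeneity
censor_max_years: 6.0
target_event_rate: 0.58
seed: 0
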