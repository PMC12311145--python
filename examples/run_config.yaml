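# Full-pipeline run configuration (all keys optional except the paths).
# Unknown keys are rejected; every value is echoed to the run log.

feature_table: demo/cohort/features.csv
clinical_table: demo/cohort/clinical.csv
out_dir: demo/results

volume_rho: 0.1            # volume de-correlation threshold |rho|
redundancy_rho: 0.7        # redundancy threshold |rho|
redundancy_order: variance_desc   # or name_asc
tsrc_threshold: 33.0       # percent volume change
tsrc_convention: reduction_all    # or no_growth_all
aggregators: [max, mean, median, sd]
zscore_scope: cohort       # or per_patient
cv_folds: 5
cv_seed: 0
c_grid: [0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]
km_split: median           # or fixed
mirv_metrics_for_models: [mirv_distance_max, mirv_dissimilarity_max]
recist_order: {CR: 0, PR: 1, SD: 2, PD: 3}
# histology_order: {}      # defaults to alphabetical levels
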