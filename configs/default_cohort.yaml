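# Default synthetic-cohort configuration for `petmba simulate`.
# All fields are optional; omitted ones fall back to the package defaults
# (see petmba.cohort.CohortConfig and docs/methods.md).  Values shown are
# the defaults that emulate the three-group study design.
cohort:
  n_hv: 57
  n_nrm: 50
  n_ae: 53
  include_cerebellum: false

  # group effects on log BP_ND (HV is the reference group)
  delta_nrm_rn: 0.13976194       # log(1.15): +15% in the raphe nuclei
  delta_nrm_proj: 0.07232066     # log(1.075): about half of the RN effect
  delta_ae_rn: 0.0
  delta_ae_proj: 0.0

  # between-individual SDs of (logK1, logVND, logBPND, logk4, logvB)
  ind_sd: [0.15, 0.20, 0.25, 0.15, 0.20]
  # TAC-level SDs, same order
  tac_sd: [0.03, 0.05, 0.05, 0.05, 0.05]

  # measurement noise: per-frame SD = noise_base * mean(clean TAC)
  #                    * region scale / NLS weight
  noise_base: 0.05
  region_noise_scale:
    RN: 3.0
    cer_wm: 1.5

  # plasma free fraction model
  fp_sd_log: 0.25
  drift_shape: none              # none | linear | smooth
  drift_linear_total: -0.30

  # scan-date assignment over the 10-year study span
  date_mode: concurrent          # concurrent | staggered
  study_span_days: 3650.0

  seed: 1
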