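{
  "config_version": "1.0",
  "n_patients": 55,
  "responder_fraction": 0.6545454545454545,
  "site_mix": {
    "lung": 0.3924050632911392,
    "lymph_node": 0.2658227848101266,
    "liver": 0.06751054852320675,
    "abdominal_other": 0.10970464135021097,
    "thoracic_other": 0.05485232067510549,
    "bone": 0.046413502109704644,
    "brain": 0.021097046413502112,
    "primary_tumour": 0.04219409282700422
  },
  "lesions_per_patient": {"min": 1, "max": 8},
  "baseline_size_mm": {
    "lung": {"median": 25.0, "sigma": 0.45},
    "lymph_node": {"median": 25.0, "sigma": 0.45},
    "liver": {"median": 31.0, "sigma": 0.40},
    "abdominal_other": {"median": 41.0, "sigma": 0.55},
    "thoracic_other": {"median": 27.0, "sigma": 0.30},
    "bone": {"median": 30.0, "sigma": 0.40},
    "brain": {"median": 20.0, "sigma": 0.40},
    "primary_tumour": {"median": 80.0, "sigma": 0.30}
  },
  "baseline_attenuation_hu": {
    "lung": {"mean": 59.0, "sd": 18.0},
    "lymph_node": {"mean": 68.0, "sd": 20.0},
    "liver": {"mean": 83.0, "sd": 14.0},
    "abdominal_other": {"mean": 65.0, "sd": 22.0},
    "thoracic_other": {"mean": 67.0, "sd": 20.0},
    "bone": {"mean": 250.0, "sd": 60.0},
    "brain": {"mean": 40.0, "sd": 10.0},
    "primary_tumour": {"mean": 70.0, "sd": 20.0}
  },
  "hu_clip": [-50.0, 400.0],
  "responder_effect": {
    "size_pct_mean": -20.0,
    "size_pct_sd": 10.0,
    "attenuation_pct_mean": -35.0,
    "attenuation_pct_sd": 12.0,
    "lesion_size_pct_sd": 10.0,
    "lesion_attenuation_pct_sd": 12.0
  },
  "nonresponder_effect": {
    "size_pct_mean": 8.0,
    "size_pct_sd": 12.0,
    "attenuation_pct_mean": -3.0,
    "attenuation_pct_sd": 10.0,
    "lesion_size_pct_sd": 10.0,
    "lesion_attenuation_pct_sd": 12.0
  },
  "pfs_months": {
    "distribution": "exponential",
    "responder_median": 14.5,
    "nonresponder_median": 3.2
  },
  "os_months": {
    "distribution": "exponential",
    "responder_median": 25.4,
    "nonresponder_median": 10.4
  },
  "followup_admin_censor_months": 45.0,
  "first_eval_months": [1.1, 3.4],
  "followup_interval_months": 3.0,
  "max_followup_scans": 3,
  "new_lesion_prob_nonresponder": 0.25,
  "cavitation_prob_lung": 0.08,
  "artefact_prob": 0.025,
  "seed": 12345
}
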