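{
  "comment": "Default mouse physiology, pinned from standard rodent physiology compilations (Brown et al. 1997 tissue volume/flow fractions; Davies & Morris 1993 cardiac output and blood volume). Volumes scale linearly with body weight; flows scale with cardiac output, itself linear in body weight. Reference animal: 20 g female mouse.",
  "reference_body_weight_g": 20.0,
  "cardiac_output_ml_min_per_g": 0.4,
  "gfr_ml_min_per_g": 0.015,
  "hematocrit": 0.45,
  "hepatocellularity_1e6_cells_per_g": 135.0,
  "volume_fraction_of_bw": {
    "lung": 0.0073,
    "heart": 0.005,
    "kidney": 0.0167,
    "liver": 0.0549,
    "spleen": 0.0035,
    "gut": 0.0422,
    "muscle": 0.384,
    "adipose": 0.07,
    "skin": 0.165,
    "bone": 0.107,
    "brain": 0.0165,
    "rest_of_body": 0.0789,
    "arterial_blood": 0.0163333333333333,
    "venous_blood": 0.0326666666666667
  },
  "flow_fraction_of_cardiac_output": {
    "heart": 0.066,
    "kidney": 0.091,
    "liver_arterial": 0.02,
    "gut": 0.141,
    "spleen": 0.01,
    "muscle": 0.159,
    "adipose": 0.07,
    "skin": 0.058,
    "bone": 0.03,
    "brain": 0.033,
    "rest_of_body": 0.322
  },
  "tissue_density_g_per_ml": {
    "default": 1.0,
    "liver": 1.05,
    "tumor": 1.0
  }
}
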