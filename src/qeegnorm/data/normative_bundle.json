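{
  "version": "1.0",
  "description": "Normative age-regression equations for resting-state qEEG features in the double-banana bipolar montage, fitted on a 37-subject healthy cohort aged 10-73 years. Polynomial coefficients are ascending in age (years); offset-exponential equations are a + b*exp(-k*years), the decaying form.",
  "n": 37,
  "age_range": [10, 73],
  "equations": {
    "pdr_frequency": {
      "kind": "polynomial",
      "coefficients": [9.77, 0.03, -0.0004, -0.000002],
      "r": 0.2977,
      "units": "Hz",
      "feature": "PDR peak frequency (either hemisphere)"
    },
    "pdr_amplitude_left": {
      "kind": "offset_exponential",
      "coefficients": [14.62, 99.31, 0.127],
      "r": 0.7011,
      "units": "uV",
      "feature": "P3-O1 RMS amplitude"
    },
    "pdr_amplitude_right": {
      "kind": "offset_exponential",
      "coefficients": [14.62, 99.32, 0.127],
      "r": 0.689,
      "units": "uV",
      "feature": "P4-O2 RMS amplitude"
    },
    "sse_L_F": {
      "kind": "polynomial",
      "coefficients": [3.2247, 0.1128, -0.0027, 2e-05],
      "r": 0.3242,
      "units": "bits",
      "feature": "Shannon spectral entropy, left frontal lobe"
    },
    "sse_R_F": {
      "kind": "polynomial",
      "coefficients": [3.0516, 0.1374, -0.0034, 2e-05],
      "r": 0.315,
      "units": "bits",
      "feature": "Shannon spectral entropy, right frontal lobe"
    },
    "sse_L_PO": {
      "kind": "polynomial",
      "coefficients": [3.3885, 0.0726, -0.0012, 5e-06],
      "r": 0.3718,
      "units": "bits",
      "feature": "Shannon spectral entropy, left parieto-occipital lobe"
    },
    "sse_R_PO": {
      "kind": "polynomial",
      "coefficients": [2.7445, 0.1229, -0.0025, 1.5e-05],
      "r": 0.4638,
      "units": "bits",
      "feature": "Shannon spectral entropy, right parieto-occipital lobe"
    },
    "sse_L_T": {
      "kind": "polynomial",
      "coefficients": [3.9949, 0.0589, -0.0014, 9.6e-06],
      "r": 0.2515,
      "units": "bits",
      "feature": "Shannon spectral entropy, left temporal lobe"
    },
    "sse_R_T": {
      "kind": "polynomial",
      "coefficients": [3.408, 0.0994, -0.0023, 1.5e-05],
      "r": 0.3658,
      "units": "bits",
      "feature": "Shannon spectral entropy, right temporal lobe"
    }
  }
}
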