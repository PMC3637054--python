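{
  "description": "Lysate-screen summary statistics for the four uricase candidates (A-D, catalytic capacity descending), n = 30 clones each. Values are [mean, SD]. Units: protein mg/mL, activity concentration U/mL, specific activity U/mg (units are a declared convention). 'ratio_purified' is the catalytic-capacity ratio measured on purified enzymes; it is carried as metadata and never recomputed from lysate simulations.",
  "n_clones": 30,
  "units": {
    "protein": "mg/mL",
    "activity_concentration": "U/mL",
    "specific_activity": "U/mg"
  },
  "candidates": {
    "A": {
      "protein": [0.63, 0.09],
      "activity_concentration": [0.30, 0.07],
      "specific_activity": [0.49, 0.09]
    },
    "B": {
      "protein": [0.66, 0.10],
      "activity_concentration": [0.28, 0.06],
      "specific_activity": [0.43, 0.05]
    },
    "C": {
      "protein": [0.65, 0.15],
      "activity_concentration": [0.18, 0.05],
      "specific_activity": [0.28, 0.05]
    },
    "D": {
      "protein": [0.66, 0.09],
      "activity_concentration": [0.033, 0.004],
      "specific_activity": [0.050, 0.006]
    }
  },
  "pairs": {
    "A-B": {"ratio_purified": 1.37},
    "B-C": {"ratio_purified": 1.58},
    "A-C": {"ratio_purified": 2.15},
    "C-D": {"ratio_purified": 1.90},
    "B-D": {"ratio_purified": 3.00},
    "A-D": {"ratio_purified": 4.10}
  }
}
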