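{
  "siyez": {
    "x1": 150, "x2": 450,
    "predicted": {"taste": 7.75, "color": 7.08, "smell": 7.67, "general_acceptance": 7.37},
    "experimental_mean": {"taste": 7.50, "color": 7.19, "smell": 7.83, "general_acceptance": 7.75},
    "experimental_sd": {"taste": 0.31, "color": 0.06, "smell": 0.38, "general_acceptance": 0.27},
    "percent_difference": {"taste": 3.22, "color": 1.52, "smell": 2.04, "general_acceptance": 4.90}
  },
  "firik": {
    "x1": 147, "x2": 435,
    "predicted": {"taste": 6.68, "color": 7.52, "smell": 8.70, "general_acceptance": 8.75},
    "experimental_mean": {"taste": 7.12, "color": 7.08, "smell": 8.46, "general_acceptance": 8.49},
    "experimental_sd": {"taste": 0.23, "color": 0.21, "smell": 0.41, "general_acceptance": 0.14},
    "percent_difference": {"taste": 6.17, "color": 5.85, "smell": 2.75, "general_acceptance": 2.97}
  },
  "karakilcik": {
    "x1": 146, "x2": 450,
    "predicted": {"taste": 7.16, "color": 7.54, "smell": 8.58, "general_acceptance": 7.76},
    "experimental_mean": {"taste": 7.23, "color": 7.68, "smell": 8.45, "general_acceptance": 7.92},
    "experimental_sd": {"taste": 0.07, "color": 0.07, "smell": 0.42, "general_acceptance": 0.10},
    "percent_difference": {"taste": 0.96, "color": 1.82, "smell": 1.51, "general_acceptance": 2.02}
  }
}
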