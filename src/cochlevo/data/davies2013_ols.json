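{
  "name": "davies2013_ols",
  "description": "Non-phylogenetic stepwise multiple-regression coefficients linking log10 echolocation call frequency (kHz) to log10 basilar membrane length (mm) and log10 number of cochlear turns across laryngeal echolocating bats.",
  "log_base": 10,
  "parameters": {
    "min":  {"intercept": 1.60, "membrane": -1.02, "turns": 2.76},
    "peak": {"intercept": 1.92, "membrane": -1.01, "turns": 2.26},
    "max":  {"intercept": 2.22, "membrane": -0.96, "turns": 1.58}
  }
}
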