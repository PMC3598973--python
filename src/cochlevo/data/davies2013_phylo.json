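{
  "name": "davies2013_phylo",
  "description": "Phylogenetically corrected multiple-regression coefficients linking log10 echolocation call frequency (kHz) to log10 basilar membrane length (mm) and log10 number of cochlear turns, fitted across laryngeal echolocating bats with a Bayesian phylogenetic mixed model.",
  "log_base": 10,
  "parameters": {
    "min":  {"intercept": 1.66, "membrane": -0.89, "turns": 2.25},
    "peak": {"intercept": 1.88, "membrane": -0.88, "turns": 2.00},
    "max":  {"intercept": 2.09, "membrane": -0.78, "turns": 1.44}
  }
}
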