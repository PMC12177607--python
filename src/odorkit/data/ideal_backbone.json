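{
  "version": "1.0",
  "comment": "Ideal protein backbone geometry (Engh & Huber style restraint targets). Bonds in Angstrom, angles in degrees; sigma = restraint standard deviation.",
  "bonds": {
    "N-CA": {"mean": 1.458, "sigma": 0.019},
    "CA-C": {"mean": 1.525, "sigma": 0.021},
    "C-O":  {"mean": 1.231, "sigma": 0.020},
    "C-N":  {"mean": 1.329, "sigma": 0.014}
  },
  "angles": {
    "N-CA-C":  {"mean": 111.2, "sigma": 2.8},
    "CA-C-N":  {"mean": 116.2, "sigma": 2.0},
    "C-N-CA":  {"mean": 121.7, "sigma": 1.8},
    "CA-C-O":  {"mean": 120.8, "sigma": 1.7},
    "O-C-N":   {"mean": 123.0, "sigma": 1.6}
  }
}
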