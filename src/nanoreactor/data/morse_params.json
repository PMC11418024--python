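{
  "_comment": "Toy reactive pair parameters. Morse: De in internal energy units (amu*A^2/fs^2, 1 unit ~ 1e4 kJ/mol), a in 1/A, re in A. Well depths/lengths are rounded spectroscopic values; these are test fixtures with roughly chemical magnitudes, not physics claims. LJ handles He (inert energy-transfer agent): eps internal units, sigma A; 'He-*' is the generic He-heavy wall.",
  "morse": {
    "H-H": {"De": 0.0432, "a": 2.00, "re": 0.741},
    "C-C": {"De": 0.0350, "a": 2.00, "re": 1.54},
    "C-H": {"De": 0.0413, "a": 1.90, "re": 1.09},
    "C-N": {"De": 0.0750, "a": 2.20, "re": 1.17},
    "N-H": {"De": 0.0391, "a": 2.10, "re": 1.01},
    "N-N": {"De": 0.0945, "a": 2.70, "re": 1.10}
  },
  "lj": {
    "He-He": {"eps": 9.0e-6, "sigma": 2.64},
    "He-*": {"eps": 5.0e-6, "sigma": 3.00}
  },
  "sato": 0.05
}
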