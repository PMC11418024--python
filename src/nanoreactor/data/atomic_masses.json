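{
  "_comment": "Isotope-averaged standard atomic weights (amu), IUPAC/CIAAW 2021 abridged values.",
  "H": 1.008,
  "He": 4.002602,
  "Li": 6.94,
  "Be": 9.0121831,
  "B": 10.81,
  "C": 12.011,
  "N": 14.007,
  "O": 15.999,
  "F": 18.998403163,
  "Ne": 20.1797,
  "Na": 22.98976928,
  "Mg": 24.305,
  "Al": 26.9815384,
  "Si": 28.085,
  "P": 30.973761998,
  "S": 32.06,
  "Cl": 35.45,
  "Ar": 39.948
}
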