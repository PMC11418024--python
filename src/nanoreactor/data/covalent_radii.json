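{
  "_comment": "Single-bond covalent radii (Angstrom) from Cordero et al., Dalton Trans. 2008, 2832-2838 (sp3 value for carbon).",
  "H": 0.31,
  "He": 0.28,
  "Li": 1.28,
  "Be": 0.96,
  "B": 0.84,
  "C": 0.76,
  "N": 0.71,
  "O": 0.66,
  "F": 0.57,
  "Ne": 0.58,
  "Na": 1.66,
  "Mg": 1.41,
  "Al": 1.21,
  "Si": 1.11,
  "P": 1.07,
  "S": 1.05,
  "Cl": 1.02,
  "Ar": 1.06
}
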