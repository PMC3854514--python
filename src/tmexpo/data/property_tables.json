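{
  "_comment": "Per-residue property tables for the feature encoder, version 1. Values are editable package defaults in the style of the cited literature scales; the three normalization anchors (Tyr volume 237.2, Cys contact propensity 1.43, Pro turn propensity 2.7) are asserted at load time. volume: A^3, divided by 237.2. polarity: hydration-potential-style values (kcal/mol, polar negative), sigmoid-encoded. charge: +1 positive, 0.5 neutral, 0 negative. contact: interhelical contact propensity, divided by 1.43. energy: apparent free energy of membrane insertion (kcal/mol, Hessa biological scale), sigmoid-encoded. amphiphilicity: interface-affinity index, sigmoid-encoded with positive sign. turn: helix turn propensity, divided by 2.7.",
  "version": 1,
  "anchors": {"volume": ["TYR", 237.2], "contact": ["CYS", 1.43], "turn": ["PRO", 2.7]},
  "volume": {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 237.2, "V": 140.0
  },
  "polarity": {
    "A": 1.94, "R": -19.92, "N": -9.68, "D": -10.95, "C": -1.24,
    "Q": -9.38, "E": -10.20, "G": 2.39, "H": -10.27, "I": 2.15,
    "L": 2.28, "K": -9.52, "M": -1.48, "F": -0.76, "P": 0.00,
    "S": -5.06, "T": -4.88, "W": -5.88, "Y": -6.11, "V": 1.99
  },
  "charge": {
    "A": 0.5, "R": 1.0, "N": 0.5, "D": 0.0, "C": 0.5,
    "Q": 0.5, "E": 0.0, "G": 0.5, "H": 0.5, "I": 0.5,
    "L": 0.5, "K": 1.0, "M": 0.5, "F": 0.5, "P": 0.5,
    "S": 0.5, "T": 0.5, "W": 0.5, "Y": 0.5, "V": 0.5
  },
  "contact": {
    "A": 1.10, "R": 0.60, "N": 0.80, "D": 0.70, "C": 1.43,
    "Q": 0.75, "E": 0.68, "G": 1.25, "H": 0.90, "I": 0.98,
    "L": 1.02, "K": 0.55, "M": 1.08, "F": 1.05, "P": 0.85,
    "S": 1.05, "T": 1.00, "W": 0.95, "Y": 0.98, "V": 0.95
  },
  "energy": {
    "A": 0.11, "R": 2.58, "N": 2.05, "D": 3.49, "C": -0.13,
    "Q": 2.36, "E": 2.68, "G": 0.74, "H": 2.06, "I": -0.60,
    "L": -0.55, "K": 2.71, "M": -0.10, "F": -0.32, "P": 2.23,
    "S": 0.84, "T": 0.52, "W": 0.30, "Y": 0.68, "V": -0.31
  },
  "amphiphilicity": {
    "A": 0.00, "R": 1.30, "N": 0.20, "D": 0.20, "C": 0.05,
    "Q": 0.30, "E": 0.20, "G": 0.00, "H": 0.80, "I": 0.05,
    "L": 0.05, "K": 1.20, "M": 0.40, "F": 0.50, "P": 0.00,
    "S": 0.10, "T": 0.10, "W": 1.90, "Y": 1.60, "V": 0.05
  },
  "turn": {
    "A": 0.50, "R": 0.80, "N": 1.40, "D": 1.30, "C": 0.70,
    "Q": 0.80, "E": 0.70, "G": 1.80, "H": 0.90, "I": 0.30,
    "L": 0.30, "K": 0.90, "M": 0.40, "F": 0.50, "P": 2.70,
    "S": 1.20, "T": 0.90, "W": 0.60, "Y": 0.70, "V": 0.30
  }
}
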