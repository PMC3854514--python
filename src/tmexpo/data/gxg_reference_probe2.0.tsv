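# Extended Gly-X-Gly reference ASA (A^2), probe 2.0 A, n_points 960.
# Computed with tmexpo's dot-sphere sampler on ideal-geometry extended
# tripeptides (see docs/methods.md); version 1.
residue	reference_asa
ALA	141.73
ARG	298.43
ASN	190.22
ASP	181.32
CYS	170.98
GLN	228.05
GLU	222.33
GLY	104.95
HIS	235.47
ILE	214.86
LEU	235.25
LYS	259.08
MET	244.49
PHE	273.82
PRO	162.70
SER	150.42
THR	174.41
TRP	322.52
TYR	286.12
VAL	186.68
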