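# Random-coil 1H-alpha chemical shifts (ppm), Wishart-style reference set,
# extended with pragmatic values for the nonstandard residues used here
# (AIB has no H-alpha: its value refers to the CH3 protons and is synthetic;
# DAB is approximated by the Lys value). For conformational-shift
# bookkeeping on synthetic data, not a curated reference.
residue	delta_rc_ppm
ALA	4.32
ARG	4.34
ASN	4.74
ASP	4.64
CYS	4.55
GLN	4.34
GLU	4.35
GLY	3.96
HIS	4.63
ILE	4.17
LEU	4.34
LYS	4.32
MET	4.48
PHE	4.62
PRO	4.42
SER	4.47
THR	4.35
TRP	4.66
TYR	4.55
VAL	4.12
AIB	1.42
DAB	4.32
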