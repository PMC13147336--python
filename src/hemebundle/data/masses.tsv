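element	mass_u
H	1.008
C	12.011
N	14.007
O	15.999
S	32.06
P	30.974
F	18.998
Cl	35.45
Fe	55.845
Co	58.933
Zn	65.38
Mn	54.938
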