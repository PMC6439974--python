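term	weight
Env	1.98
Pair	2.02
Vdw	0.72
Hs	0.82
Ss	0.37
Sheet	1.90
R-sigma	1.11
Cb	0.24
Rg	2.63
Co	0.00
Ramachandran	0.43
Hb-srbb	0.80
Hb-lrbb	0.00
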