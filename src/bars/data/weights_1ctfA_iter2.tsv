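term	weight
Env	0.97
Pair	1.22
Vdw	0.88
Hs	1.70
Ss	1.00
Sheet	1.00
R-sigma	1.00
Cb	0.01
Rg	3.14
Co	1.05
Ramachandran	0.00
Hb-srbb	0.02
Hb-lrbb	0.00
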