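term	weight
Env	5.69
Pair	1.09
Vdw	0.20
Hs	1.28
Ss	0.20
Sheet	1.14
R-sigma	0.19
Cb	1.62
Rg	0.31
Co	0.62
Ramachandran	0.27
Hb-srbb	0.36
Hb-lrbb	0.00
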