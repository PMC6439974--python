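term	weight
Env	1.00
Pair	1.00
Vdw	1.00
Hs	1.00
Ss	1.00
Sheet	1.00
R-sigma	1.00
Cb	1.00
Rg	3.00
Co	1.00
Ramachandran	0.00
Hb-srbb	0.00
Hb-lrbb	0.00
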