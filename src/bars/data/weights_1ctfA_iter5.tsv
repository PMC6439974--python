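term	weight
Env	1.26
Pair	2.62
Vdw	0.55
Hs	0.09
Ss	0.48
Sheet	3.48
R-sigma	0.53
Cb	0.00
Rg	0.49
Co	0.00
Ramachandran	1.01
Hb-srbb	2.49
Hb-lrbb	0.00
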