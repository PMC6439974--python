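term	weight
Env	0.48
Pair	0.64
Vdw	0.61
Hs	1.06
Ss	0.48
Sheet	1.00
R-sigma	0.53
Cb	0.41
Rg	6.05
Co	0.74
Ramachandran	0.01
Hb-srbb	0.00
Hb-lrbb	0.00
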