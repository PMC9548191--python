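# Plastid-associated genes found only in the photosynthetic C. curvata strains.
cpeT-like
fkbp
fkbp-like
hcf136
hlip
met
rubredoxin
sut
tha4
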