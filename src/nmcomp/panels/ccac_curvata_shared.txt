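# Genes shared between the colorless CCAC1634B strain and photosynthetic
# C. curvata but missing from both C. paramecium strains (19 genes).
bre1-like
cdc2-like
crm
gyrA
gyrB
hat
hira
kin-mps1
psf2
ranbpm
rps21
rrp40
rrp41
rrp44
smc2
smc4
spt5
U5snRNP-20kDa
ubc2
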