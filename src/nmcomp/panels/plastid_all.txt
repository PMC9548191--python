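# Full 31-gene plastid-associated panel: the 16-gene core, the 9
# photosynthesis-only genes, and the variably retained remainder.
clpP1
clpP2
cpn60
dnaG
engA
ftsZ
gidA
gidB
iap100
rpoD
rps15
secE
sufD
tic22
orf152
orf826
cpeT-like
fkbp
fkbp-like
hcf136
hlip
met
rubredoxin
sut
tha4
cbbX
ycf20
orf177
orf243
orf268
orf336
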