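# Plastid-associated genes retained by all cryptophyte nucleomorph genomes,
# including the non-photosynthetic Cryptomonas strains (16 genes).
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
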