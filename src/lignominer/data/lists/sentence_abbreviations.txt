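# tokens after which a period does not end a sentence
sp
spp
al
et
cf
vs
fig
figs
eg
ie
e
i
g
dr
prof
no
ca
approx
var
subsp
str
cv
ser
mol
wt
vol
resp
ref
refs
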