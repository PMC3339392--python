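# common English -ase/-ases words that are not enzymes
disease
increase
decrease
release
purchase
phase
base
case
cease
lease
please
phrase
database
showcase
staircase
suitcase
erase
baseline
encase
ukase
diastase-free
grease
crease
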