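# head nouns for generic organism mentions (preceded by an adjective)
fungus
fungi
yeast
yeasts
bacterium
bacteria
mold
molds
mould
moulds
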