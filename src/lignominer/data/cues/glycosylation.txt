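# glycosylation morphemes; trailing * = prefix match
glycosyl*
deglycosyl*
N-linked
O-linked
glycoprotein
glycan
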