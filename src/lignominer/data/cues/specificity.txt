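# substrate-specificity vocabulary
highest activity on
specificity
specific for
most active on
preferred substrate
broad substrate range
hydrolyzed
no activity toward
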