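# expression-host cue phrases; a cue must closely precede the organism
expressed in
produced in
overexpressed in
heterologously expressed in
expression host
host strain
host
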