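# fixed phrases containing organism words that are never organism mentions
bovine serum albumin
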