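# activity-assay condition vocabulary
assay
assays
assayed
reaction mixture
buffer
carried out
standard conditions
reaction was performed
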