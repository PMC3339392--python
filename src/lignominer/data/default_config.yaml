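# Default pipeline configuration. Paths are resolved against the packaged
# data directory unless absolute. Flat key/value only; unknown keys rejected.
enzyme_lexicon: lexicons/enzymes.tsv
taxon_lexicon: lexicons/taxa.tsv
substrate_lexicon: lexicons/substrates.tsv
assay_lexicon: lexicons/assays.tsv
ase_stoplist: lists/ase_stoplist.txt
organism_blocklist: lists/organism_blocklist.txt
host_cues: lists/host_cues.txt
generic_organism_cues: lists/generic_organism_cues.txt
sentence_abbreviations: lists/sentence_abbreviations.txt
cue_activity_stability: cues/activity_stability.txt
cue_kinetic: cues/kinetic.txt
cue_assay_conditions: cues/assay_conditions.txt
cue_glycosylation: cues/glycosylation.txt
cue_specificity: cues/specificity.txt
cue_product: cues/product.txt
enzyme_url_template: "https://www.brenda-enzymes.org/enzyme.php?ecno={ec}"
taxon_url_template: "https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id={taxid}"
generic_organism_mentions: true
host_detection: true
rdf_format: turtle
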