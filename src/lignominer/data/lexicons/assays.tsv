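name	synonyms	url
Dinitrosalicylic Acid Method	DNS method|dinitrosalicylic acid assay	
Somogyi-Nelson method	Nelson-Somogyi method	
Lowry method	Lowry assay	
Bradford assay	Bradford method	
bicinchoninic acid assay	BCA assay	
p-nitrophenol assay		
azo-dye assay		
viscometric assay		
ABTS assay		
plate clearing assay		
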