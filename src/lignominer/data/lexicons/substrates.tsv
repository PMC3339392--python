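name	synonyms	url
stachyose		
raffinose		
melibiose		
cellopentaose		
cellotetraose		
cellotriose		
cellobiose		
carboxymethyl cellulose	CMC	
Avicel	microcrystalline cellulose	
beechwood xylan		
birchwood xylan		
oat spelt xylan		
xylan		
locust bean gum		
guar gum		
laminarin		
lichenan		
starch	soluble starch	
pectin		
chitin		
mannan		
filter paper		
p-nitrophenyl-beta-D-glucopyranoside	pNPG	
olive oil		
tributyrin		
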