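# reaction-product / identification vocabulary
products
product
HPLC
TLC
thin-layer chromatography
released
liberated
hydrolysis products
end-products
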