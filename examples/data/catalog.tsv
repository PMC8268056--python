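gene_symbol	localization
ADAM9	extracellular;transmembrane
ADAM10	transmembrane
CTSB	lysosome;secreted
CTSD	lysosome;secreted
MMP2	extracellular;secreted
PRSS1	secreted;extracellular
HTRA1	secreted
CAPN1	cytoplasm
CASP3	cytoplasm
USP7	nucleus
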