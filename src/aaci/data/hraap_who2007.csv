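amino_acid,level
isoleucine,30
leucine,59
lysine,45
methionine,16
cysteine,6
phenylalanine,25
tyrosine,13
threonine,23
tryptophan,6
valine,39
histidine,15
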