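stage,metastasis,no_metastasis
II,11,22
IIIA,8,22
IIIB,15,11
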