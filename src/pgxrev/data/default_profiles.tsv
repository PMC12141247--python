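# Phenotypes assumed for genes absent from a recommendation query profile.
gene	phenotype
CYP2C9	Normal Metabolizer
ABCG2	Normal Metabolizer
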