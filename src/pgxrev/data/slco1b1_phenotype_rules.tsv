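# Unordered function-pair -> phenotype rules for the SLCO1B1 transporter.
gene	function_a	function_b	phenotype
SLCO1B1	normal function	normal function	Normal function
SLCO1B1	normal function	decreased function	Decreased function
SLCO1B1	normal function	no function	Decreased function
SLCO1B1	decreased function	decreased function	Poor function
SLCO1B1	decreased function	no function	Poor function
SLCO1B1	no function	no function	Poor function
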