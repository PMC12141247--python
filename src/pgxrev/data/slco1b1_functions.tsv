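# Synthetic fixture: per-allele function assignments for SLCO1B1 chosen so
# the shipped tables reproduce the published diplotype-level phenotypes
# (*1/*1 -> Normal function, *31/*37 -> Decreased function).  These are
# fixture data, not PharmVar/CPIC allele annotations.
gene	allele	function
SLCO1B1	*1	normal function
SLCO1B1	*37	normal function
SLCO1B1	*31	no function
SLCO1B1	*5	decreased function
SLCO1B1	*15	decreased function
SLCO1B1	*20	normal function
SLCO1B1	*27	normal function
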