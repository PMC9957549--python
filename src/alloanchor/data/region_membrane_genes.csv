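gene_id,chrom,start,end,components
ARSD,1,129735000,129760000,integral component of membrane
ARSE,1,129770000,129792000,integral component of membrane
CD99,1,129863000,129876000,integral component of membrane;plasma membrane;cell surface
P2RY8,1,129950000,129980000,integral component of membrane;plasma membrane
SLC25A6,1,130050000,130065000,integral component of membrane
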