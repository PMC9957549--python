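assay_id,chrom,position,gene_location,ref_allele,alt_allele,variant_class,coding_effect,aa_change
rs74153692,1,129875094,2,G,A,snp,missense,V27M
rs314496839,1,129871024,3,G,A,snp,missense,V37I
rs312634736,1,129870489,4,G,A,snp,missense,G48D
rs316308207,1,129867634,7,T,C,snp,synonymous,G95G
rs10730300,1,129867625,7,A,G,snp,synonymous,P98P
rs735363747,1,129866188,8,A,G,snp,missense,E124G
rs13623448,1,129866100,intron,ref,del,indel,splice_region,
rs735519530,1,129864266,11,T,C,snp,synonymous,L185L
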