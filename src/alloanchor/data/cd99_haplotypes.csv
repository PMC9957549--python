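label,rs74153692,rs314496839,rs312634736,rs316308207,rs10730300,rs735363747,rs13623448,rs735519530,serology
CD99-H01,G,A,G,C,A,A,del,T,D1
CD99-H02,G,G,A,C,A,A,del,T,D2
CD99-H03,G,G,G,C,G,A,ref,T,D3
CD99-H04,G,G,G,C,A,A,ref,T,D3
CD99-H05,G,A,A,C,A,A,ref,T,
CD99-H06,G,G,G,T,G,A,ref,T,D3
CD99-H07,A,G,G,C,A,A,del,T,
CD99-H08,G,G,G,T,A,A,del,T,
CD99-H09,G,A,A,T,A,A,del,T,
CD99-H10,G,G,G,T,A,A,ref,T,
CD99-H11,G,A,G,C,A,A,del,C,
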