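target_gene	forward	reverse
cdr-2	CGAGCCTCATTTGGAAAGAA	GCATCTGCCGCTGTAACTTT
F15B9.10	CCGGACAGTTTCAAGAATGC	CACTGAGGATCCAATGTCCA
hrg-9	TGGAATATTGAGTGGCGTTG	CCTCCTCTACTTGGTGCATGT
C07G1.7	GCTGAAGAAGCTTCAACCGTAG	TCTCGTGTCAATTCCGGTCT
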