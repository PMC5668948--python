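class	subfamily	position	ref	alt
ALU	AluYa5	21	T	C
ALU	AluYa5	54	G	A
ALU	AluYa5	64	A	G
ALU	AluYa5	66	C	T
ALU	AluYa5	223	T	C
ALU	AluYb8	55	C	T
ALU	AluYb8	88	A	G
ALU	AluYb8	107	G	A
ALU	AluYb8	121	A	G
ALU	AluYb8	158	G	A
ALU	AluYb8	222	C	T
ALU	AluYb8	228	G	A
ALU	AluYb8	249	G	A
LINE1	L1-Ta	691	A	G
LINE1	L1-Ta	2046	A	G
LINE1	L1-Ta	2627	C	T
LINE1	L1-Ta1d	691	A	G
LINE1	L1-Ta1d	1903	T	C
LINE1	L1-Ta1d	2046	A	G
LINE1	L1-Ta1d	2627	C	T
LINE1	L1-Ta1d	3527	C	T
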