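motif_class	aa5	aa_last
P	T	D
L	P	D
S	N	D
P	N	N
L	P	D
S	T	N
P	S	N
L	N	D
S	N	S
P2	T	D
L2	P	D
S2	N	N
E1	T	R
E2	G	N
DYW	D	W
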