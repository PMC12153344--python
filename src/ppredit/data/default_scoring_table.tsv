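pair	A	C	G	U
TD	-0.5	-0.3	1.2	-0.4
TN	1.1	-0.4	-0.2	-0.5
ND	-0.6	-0.2	-0.4	1.3
NN	-0.3	1.0	-0.5	-0.2
SN	1.0	-0.2	-0.4	-0.3
NS	-0.4	1.1	-0.3	-0.2
PD	-0.5	-0.1	-0.6	1.2
SD	-0.4	-0.2	0.9	-0.3
TR	0.4	0.1	-0.2	-0.1
GN	0.5	-0.1	0.2	-0.3
AD	-0.3	0.2	-0.4	0.8
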