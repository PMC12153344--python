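site	sample1	sample2	sample3	sample4	sample5	sample6	sample7	sample8	sample9	sample10	sample11	sample14	n_samples	is_target
rpoA	62.31*	71.0*	30.2*	57.3*	59.1*	81.9*	78.5*	68.0*	58.1*	22.7*	15.6*	4.5*	12	1
301209	10.4*	17.8*		7.6		17.1*	12.3*	21.9					4	0
433327	5.4					22.9*							1	0
779169	10.7*												1	0
846395	1.2*	0.7		0.2		1.1		0.9					1	0
957341	0.4	1.0*		0.4	0.2	0.9	0.4	1.3					1	0
998460	5.2				10.9*	3.2							1	0
1115962	0.8	1.1*		0.7	0.5	2.7*	1.1	1.6	0.6				2	0
1610233	3.8					25.0*		17.5*					2	0
1650242						2.3*	0.6						1	0
1724437	6.5	13.7*			14.8*	18.2*							3	0
1821466	38.5*	14.9*		10.9*		25.0	28.0*	46.7*	20.0				5	0
1838803	14.6*	10.1*	0.9	6.8*	6.0*	20.3*	11.1*	18.3*	9.4*		0.4		8	0
1941416	16.8*	21.8*		6.0	14.3*	37.4*	26.6*	33.9*	9.3				6	0
1967867		10.8*				24.0*	14.7*						3	0
2437684	4.4	14.0*				18.6*	11.3*						3	0
2469966	5.3*					7.5							1	0
2728082	6.1*	2.2*		5.0*		1.3	0.8	0.9					3	0
2728396	0.8	1.5	0.8	0.8	1.6	2.0	2.0*	2.0	1.0	1.0	0.6	0.1	1	0
2767599	7.5*	6.0*		5.7	2.4	32.9*	12.5*	13.4*	10.1*				6	0
3018155	1.8	13.2*											1	0
3146210	2.1*	1.4		1.0	0.5	1.3	0.3	1.4	0.6				1	0
3248710	11.1*	3.5		5.3	4.2	46.6*	18.2*	9.1	5.7				3	0
3406026	1.8	1.5		1.0	0.9	6.9*	2.3	2.6	1.0				1	0
3960072	3.7	3.4		1.4	1.8	14.1*	8.7*	4.1	2.7				2	0
4036064	0.6	1.4*		0.5	0.7	1.1	0.5	1.2	0.6	0.3			1	0
4058658	1.4*	0.6		0.8	0.4	2.1*	0.6	2.0*	1.1*				4	0
4118470	9.7*												1	0
4145999	1.0	1.5*		0.8	0.4	0.7	0.4	1.2	0.4				1	0
4148094	7.3*	5.1*		4.7	3.7	14.1*	8.2*	8.1	3.2	0.9	1.0		4	0
4258541	38.1*	41.6*		16.5*	46.8*	41.5*	45.2*	45.7*	23.2*				8	0
4289975	10.0*					21.9							1	0
4350628	0.6	1.8*		0.4	0.2	3.0*	2.9*	0.3					3	0
4471230						21.2*							1	0
4495686	5.8*	5.4*		2.6	4.9	7.1	7.4	4.4					2	0
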