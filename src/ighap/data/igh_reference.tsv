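gene	locus	functionality	order	canonical
IGHV6-1	IGHV	functional	1	IGHV6-1
IGHV1-2	IGHV	functional	2	IGHV1-2
IGHV1-3	IGHV	functional	3	IGHV1-3
IGHV4-4	IGHV	functional	4	IGHV4-4
IGHV7-4-1	IGHV	functional	5	IGHV7-4-1
IGHV2-5	IGHV	functional	6	IGHV2-5
IGHV3-6	IGHV	pseudo	7	IGHV3-6
IGHV3-7	IGHV	functional	8	IGHV3-7
IGHV1-8	IGHV	functional	9	IGHV1-8
IGHV3-9	IGHV	functional	10	IGHV3-9
IGHV5-10-1	IGHV	functional	11	IGHV5-10-1
IGHV3-11	IGHV	functional	12	IGHV3-11
IGHV3-13	IGHV	functional	13	IGHV3-13
IGHV3-15	IGHV	functional	14	IGHV3-15
IGHV3-16	IGHV	ORF	15	IGHV3-16
IGHV1-18	IGHV	functional	16	IGHV1-18
IGHV3-20	IGHV	functional	17	IGHV3-20
IGHV3-21	IGHV	functional	18	IGHV3-21
IGHV3-22	IGHV	pseudo	19	IGHV3-22
IGHV3-23	IGHV	functional	20	IGHV3-23
IGHV1-24	IGHV	functional	21	IGHV1-24
IGHV3-25	IGHV	pseudo	22	IGHV3-25
IGHV2-26	IGHV	functional	23	IGHV2-26
IGHV4-28	IGHV	functional	24	IGHV4-28
IGHV3-30	IGHV	functional	25	IGHV3-30
IGHV4-30-1	IGHV	functional	26	IGHV4-30-1
IGHV4-30-2	IGHV	functional	27	IGHV4-30-2
IGHV3-30-3	IGHV	functional	28	IGHV3-30-3
IGHV4-31	IGHV	functional	29	IGHV4-31
IGHV3-33	IGHV	functional	30	IGHV3-33
IGHV4-34	IGHV	functional	31	IGHV4-34
IGHV3-35	IGHV	ORF	32	IGHV3-35
IGHV3-38	IGHV	ORF	33	IGHV3-38
IGHV4-38-2	IGHV	functional	34	IGHV4-38-2
IGHV3-43	IGHV	functional	35	IGHV3-43
IGHV1-45	IGHV	functional	36	IGHV1-45
IGHV1-46	IGHV	functional	37	IGHV1-46
IGHV3-47	IGHV	pseudo	38	IGHV3-47
IGHV3-48	IGHV	functional	39	IGHV3-48
IGHV3-49	IGHV	functional	40	IGHV3-49
IGHV5-51	IGHV	functional	41	IGHV5-51
IGHV3-52	IGHV	pseudo	42	IGHV3-52
IGHV3-53	IGHV	functional	43	IGHV3-53
IGHV1-58	IGHV	functional	44	IGHV1-58
IGHV4-59	IGHV	functional	45	IGHV4-59
IGHV4-61	IGHV	functional	46	IGHV4-61
IGHV3-62	IGHV	pseudo	47	IGHV3-62
IGHV3-64	IGHV	functional	48	IGHV3-64
IGHV3-64D	IGHV	functional	49	IGHV3-64D
IGHV3-66	IGHV	functional	50	IGHV3-66
IGHV1-69	IGHV	functional	51	IGHV1-69
IGHV1-69D	IGHV	functional	52	IGHV1-69D
IGHV1-69-2	IGHV	functional	53	IGHV1-69-2
IGHV2-70	IGHV	functional	54	IGHV2-70
IGHV3-71	IGHV	ORF	55	IGHV3-71
IGHV3-72	IGHV	functional	56	IGHV3-72
IGHV3-73	IGHV	functional	57	IGHV3-73
IGHV3-74	IGHV	functional	58	IGHV3-74
IGHV7-81	IGHV	ORF	59	IGHV7-81
IGHD1-1	IGHD	functional	1	IGHD1-1
IGHD2-2	IGHD	functional	2	IGHD2-2
IGHD3-3	IGHD	functional	3	IGHD3-3
IGHD4-4	IGHD	functional	4	IGHD4-11
IGHD5-5	IGHD	functional	5	IGHD5-18
IGHD6-6	IGHD	functional	6	IGHD6-6
IGHD1-7	IGHD	functional	7	IGHD1-7
IGHD2-8	IGHD	functional	8	IGHD2-8
IGHD3-9	IGHD	functional	9	IGHD3-9
IGHD3-10	IGHD	functional	10	IGHD3-10
IGHD4-11	IGHD	functional	11	IGHD4-11
IGHD5-12	IGHD	functional	12	IGHD5-12
IGHD6-13	IGHD	functional	13	IGHD6-13
IGHD1-14	IGHD	functional	14	IGHD1-14
IGHD2-15	IGHD	functional	15	IGHD2-15
IGHD3-16	IGHD	functional	16	IGHD3-16
IGHD4-17	IGHD	functional	17	IGHD4-17
IGHD5-18	IGHD	functional	18	IGHD5-18
IGHD6-19	IGHD	functional	19	IGHD6-19
IGHD1-20	IGHD	functional	20	IGHD1-20
IGHD2-21	IGHD	functional	21	IGHD2-21
IGHD3-22	IGHD	functional	22	IGHD3-22
IGHD4-23	IGHD	ORF	23	IGHD4-23
IGHD5-24	IGHD	ORF	24	IGHD5-24
IGHD6-25	IGHD	functional	25	IGHD6-25
IGHD1-26	IGHD	functional	26	IGHD1-26
IGHD7-27	IGHD	functional	27	IGHD7-27
IGHJ1	IGHJ	functional	1	IGHJ1
IGHJ2	IGHJ	functional	2	IGHJ2
IGHJ3	IGHJ	functional	3	IGHJ3
IGHJ4	IGHJ	functional	4	IGHJ4
IGHJ5	IGHJ	functional	5	IGHJ5
IGHJ6	IGHJ	functional	6	IGHJ6
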