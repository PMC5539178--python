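roi_index	orig_index	x	y	z	network
1	16	10	-2	45	Sensorimotor Hand
2	17	-7	-21	65	Sensorimotor Hand
3	18	-7	-33	72	Sensorimotor Hand
4	19	13	-33	75	Sensorimotor Hand
5	20	-54	-23	43	Sensorimotor Hand
6	21	29	-17	71	Sensorimotor Hand
7	22	10	-46	73	Sensorimotor Hand
8	23	-23	-30	72	Sensorimotor Hand
9	24	-40	-19	54	Sensorimotor Hand
10	25	29	-39	59	Sensorimotor Hand
11	26	50	-20	42	Sensorimotor Hand
12	27	-38	-27	69	Sensorimotor Hand
13	28	20	-29	60	Sensorimotor Hand
14	29	44	-8	57	Sensorimotor Hand
15	30	-29	-43	61	Sensorimotor Hand
16	31	10	-17	74	Sensorimotor Hand
17	32	22	-42	69	Sensorimotor Hand
18	33	-45	-32	47	Sensorimotor Hand
19	34	-21	-31	61	Sensorimotor Hand
20	35	-13	-17	75	Sensorimotor Hand
21	36	42	-20	55	Sensorimotor Hand
22	37	-38	-15	69	Sensorimotor Hand
23	38	-16	-46	73	Sensorimotor Hand
24	39	2	-28	60	Sensorimotor Hand
25	40	3	-17	58	Sensorimotor Hand
26	41	38	-17	45	Sensorimotor Hand
27	186	47	10	33	Fronto-parietal Control
28	187	-41	6	33	Fronto-parietal Control
29	188	-42	38	21	Fronto-parietal Control
30	189	38	43	15	Fronto-parietal Control
31	190	49	-42	45	Fronto-parietal Control
32	191	-28	-58	48	Fronto-parietal Control
33	192	44	-53	47	Fronto-parietal Control
34	193	32	14	56	Fronto-parietal Control
35	194	37	-65	40	Fronto-parietal Control
36	195	-42	-55	45	Fronto-parietal Control
37	196	40	18	40	Fronto-parietal Control
38	197	-34	55	4	Fronto-parietal Control
39	198	-42	45	-2	Fronto-parietal Control
40	199	33	-53	44	Fronto-parietal Control
41	200	43	49	-2	Fronto-parietal Control
42	201	-42	25	30	Fronto-parietal Control
43	202	-3	26	44	Fronto-parietal Control
44	206	31	33	26	Salience Network
45	207	48	22	10	Salience Network
46	208	-35	20	0	Salience Network
47	209	36	22	3	Salience Network
48	210	37	32	-2	Salience Network
49	211	34	16	-8	Salience Network
50	212	-11	26	25	Salience Network
51	213	-1	15	44	Salience Network
52	214	-28	52	21	Salience Network
53	215	0	30	27	Salience Network
54	216	5	23	37	Salience Network
55	217	10	22	27	Salience Network
56	218	31	56	14	Salience Network
57	219	26	50	27	Salience Network
58	220	-39	51	17	Salience Network
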