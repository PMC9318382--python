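sample_id	cp	dm4	hm1	cm2	pm2	cp_indirect
1	54.0	62.3	/	/	/	NA
2	56.1	80.1	/	/	/	NA
3	60.5	84.2	/	/	/	NA
4	55.3	57.8	/	/	/	NA
5	0.2	/	0.2	52.3	/	NA
6	/	/	/	59.9	/	NA
7	/	/	/	43.5	/	NA
8	0.2	/	1.6	6.2	0.0	NA
9	61.4	89.4	/	/	/	NA
10	57.3	91.2	/	/	/	NA
11	74.2	66.3	/	/	/	NA
12	53.3	57.4	/	/	/	NA
13	70.9	69.9	/	/	/	NA
14	/	/	/	54.3	/	NA
15	/	/	/	39.0	/	NA
16	75.7	77.3	/	/	/	NA
17	66.0	78.8	/	/	/	NA
18	71.5	67.1	/	/	/	NA
19	/	/	/	49.0	/	NA
20	/	/	/	29.0	/	NA
21	/	/	/	47.4	/	NA
22	/	/	/	63.3	/	NA
23	/	/	/	45.5	/	NA
24	66.5	69.0	/	/	/	NA
25	76.2	70.4	/	/	/	NA
26	69.5	57.0	/	/	/	NA
27	12.6	2.1	18.5	/	47.4	2.8
28	/	/	/	49.3	/	NA
29	/	/	/	40.2	0.1	NA
30	/	/	/	67.4	/	NA
31	66.8	74.5	/	/	/	NA
32	66.7	72.9	/	/	/	NA
33	0.5	/	0.6	31.5	/	NA
34	/	/	/	46.3	/	NA
35	48.6	78.9	/	/	/	NA
36	70.8	63.3	4.1	/	/	NA
37	19.3	/	26.3	/	33.5	5.5
38	/	/	/	73.4	/	NA
39	59.9	91.9	/	/	/	NA
40	44.3	70.2	/	/	/	NA
41	72.1	64.6	/	/	/	NA
42	/	/	/	42.2	/	NA
43	/	/	/	44.9	/	NA
44	31.9	6.4	40.4	38.7	/	11.2
45	/	/	/	47.8	/	NA
46	70.1	66.5	/	/	/	NA
47	70.7	57.4	/	/	/	NA
48	98.3	98.8	/	/	/	NA
49	/	/	/	47.0	/	NA
50	69.9	88.0	/	/	/	NA
51	13.4	/	21.4	/	42.7	2.2
52	96.3	96.1	/	/	/	NA
53	/	/	/	44.4	/	NA
54	68.2	55.5	/	/	/	NA
55	50.8	61.8	/	/	/	NA
56	74.8	70.7	/	/	/	NA
57	53.7	72.1	/	/	/	NA
58	/	/	/	46.9	/	NA
59	/	/	/	65.7	/	NA
60	/	/	/	82.9	/	NA
61	/	/	/	62.7	/	NA
62	80.5	69.6	/	/	/	NA
63	51.4	71.7	/	/	/	NA
64	/	/	/	70.8	/	NA
65	/	/	/	56.3	/	NA
66	/	/	/	69.4	/	NA
67	72.7	71.9	/	/	/	NA
68	79.9	75.9	/	/	/	NA
69	/	/	/	53.0	/	NA
70	/	/	/	59.3	/	NA
71	78.5	/	107.7	/	/	14.7
72	70.8	77.8	/	/	/	NA
73	/	/	/	41.7	/	NA
74	61.2	70.9	/	/	/	NA
75	53.8	60.3	/	/	/	NA
76	50.2	71.8	/	/	/	NA
77	/	/	0.3	54.1	/	NA
78	/	/	/	45.7	/	NA
79	/	/	/	60.3	/	NA
80	/	/	/	65.0	/	NA
81	83.9	73.8	/	/	/	NA
82	/	/	/	71.0	/	NA
83	57.6	87.9	/	/	/	NA
84	85.3	76.2	/	/	/	NA
85	77.8	71.4	/	/	/	NA
86	53.2	57.6	/	/	/	NA
87	/	/	/	52.4	/	NA
88	/	/	/	29.1	/	NA
89	/	/	/	47.9	/	NA
90	/	/	/	43.7	/	NA
91	75.0	68.2	/	/	/	NA
92	80.6	68.2	/	/	/	NA
93	59.9	56.3	/	/	/	NA
94	67.7	74.7	/	/	/	NA
95	0.9	/	1.3	47.5	/	NA
96	/	/	/	40.9	/	NA
97	/	/	/	46.5	/	NA
98	/	/	/	44.3	/	NA
99	69.7	53.4	/	/	/	NA
100	79.6	5.7	105.9	/	/	26.2
101	71.8	6.3	99.3	/	/	21.8
102	60.9	71.4	/	/	/	NA
103	52.4	/	78.5	/	/	12.7
104	34.3	/	46.5	/	/	10.5
105	63.2	3.9	107.8	/	/	8.9
106	3.0	/	24.1	/	/	/
107	93.6	92.8	/	/	/	NA
108	/	/	/	/	/	NA
109	62.8	90.4	/	/	/	NA
110	20.2	32.6	/	/	/	NA
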