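no	mz	charge	donkey	horse	cattle	pig
1	393.2	2	1	1	1	0
2	469.244	2	1	1	0	0
3	469.25	2	1	1	0	0
4	523.2746	2	1	1	1	1
5	539.774	2	1	1	0	0
6	539.8	2	1	1	0	0
7	570.2882	2	1	1	1	1
8	570.2891	2	1	1	1	1
9	618.35	2	1	1	0	0
10	618.795	2	1	1	0	0
11	631.8045	2	0	0	0	0
12	649.3408	3	1	1	0	0
13	660.3151	2	0	0	0	0
14	661.5864	4	0	0	0	0
15	664.8349	2	1	1	1	1
16	680.3351	2	0	0	0	0
17	690.6957	3	0	0	0	0
18	724.8451	2	0	0	0	0
19	733.3581	2	1	1	0	0
20	751.3628	2	0	0	0	0
21	765.8	2	0	0	0	0
22	765.8556	2	1	1	0	0
23	765.867	2	1	1	0	0
24	765.9142	2	1	1	0	0
25	766.4	2	1	1	0	0
26	767.7234	3	0	0	0	0
27	802.9325	2	1	1	0	0
28	806.1683	4	0	0	0	0
29	902.4576	2	1	1	0	0
30	910.4554	2	0	0	0	0
31	921.4649	2	1	1	0	0
32	1073.08	2	0	0	0	0
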