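marker_id	species	precursor_mz	rt	charge	fragmentor	product_mz	collision_energy	role
DM4	donkey	766.6	6.8	3	140	535.2	30	quantifier
DM4	donkey	766.6	6.8	3	140	478.2	30	qualifier
DM3	donkey	761.4	7.2	3	160	598.3	20	quantifier
DM3	donkey	761.4	7.2	3	160	478.2	30	qualifier
CP469	donkey	469.3	2.8	2	110	712.3	10	quantifier
CP469	donkey	469.3	2.8	2	110	783.4	15	qualifier
CP618	donkey	618.4	2.8	2	130	779.4	20	quantifier
CP618	donkey	618.4	2.8	2	130	850.4	20	qualifier
HM1	horse	386.3	2.0	2	90	499.3	3	quantifier
HM1	horse	386.3	2.0	2	90	556.3	5	qualifier
CM2	cattle	604.8	4.8	2	130	910.5	25	quantifier
CM2	cattle	604.8	4.8	2	130	570.3	20	qualifier
CM1	cattle	596.8	5.3	2	140	447.8	15	quantifier
CM1	cattle	596.8	5.3	2	140	570.3	20	qualifier
PM2	pig	490.5	3.2	2	80	566.2	5	quantifier
PM2	pig	490.5	3.2	2	80	807.5	10	qualifier
PM5	pig	773.9	5.0	2	180	977.6	30	quantifier
PM5	pig	773.9	5.0	2	180	556.3	35	qualifier
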