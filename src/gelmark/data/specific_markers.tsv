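marker_id	species	mz	rt	charge
DM1	donkey	518.2695	18.92	4
DM2	donkey	675.6632	23.36	3
DM3	donkey	761.3672	24.24	3
DM4	donkey	766.6952	23.36	3
DM5	donkey	774.0218	23.36	3
DM6	donkey	784.3392	23.36	3
DM7	donkey	854.0603	27.08	3
HM1	horse	386.2108	10.36	2
CM1	cattle	596.8454	18.90	2
CM2	cattle	604.8556	17.84	2
CM3	cattle	766.8957	18.34	2
PM1	pig	419.2446	14.04	2
PM2	pig	490.5942	14.40	3
PM3	pig	693.8432	26.70	2
PM4	pig	713.6902	17.79	3
PM5	pig	773.9237	18.51	2
PM6	pig	774.9121	17.79	2
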