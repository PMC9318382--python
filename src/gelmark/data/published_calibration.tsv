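marker_id	slope	intercept	r2	lod_mg	loq_mg
DM4	44.607	49.776	0.9992	0.05	0.16
HM1	124.66	151.13	0.9961	0.02	0.08
CM2	106.14	157.72	0.9927	0.02	0.08
PM2	299.07	162.53	0.9991	0.03	0.09
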