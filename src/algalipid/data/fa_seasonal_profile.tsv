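# Total fatty acid profile (GC-MS of FAMEs) of Fucus vesiculosus in winter
# and spring: mean weight % and SD over six replicates (2 analytical x 3
# extracts).  "Others" pools FAs with relative abundance < 0.5%
# (15:0, 16:2, 16:3, 16:4, 17:0, 17:1, 20:1); its double-bond content is
# undefined and it is excluded from index computations.
fa	winter_mean	winter_sd	spring_mean	spring_sd
14:0	10.9	1.08	6.58	1.48
16:0	17.2	1.98	20.8	2.12
16:1n-7	1.55	0.05	1.41	0.1
18:0	1.64	0.25	6.09	0.43
18:1	25.3	0.69	28.1	1.44
18:2n-6	8.78	0.22	6.62	0.49
18:3n-6	0.89	0.41	0.7	0.11
18:3n-3	7.13	0.58	3.92	0.34
18:4n-3	4.35	0.51	2.71	0.19
20:0	0.35	0.11	0.59	0.14
20:2n-6	0.71	0.04	0.7	0.15
20:3n-6	0.71	0.09	0.7	0.17
20:4n-6	10.7	0.96	13.5	1.81
20:5n-3	6.69	0.94	4.75	0.47
22:0	0.5	0.07	0.65	0.25
24:0	1.11	0.23	0.90	0.22
Others	1.49		1.30
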