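sample_id	track	maternal_gt	fetal_fraction	vaf	n_molecules	published_lr	published_call	neonate_gt
35A	paternal	0/0	0.088	0.004	1159	1.5e+09	0/0	0/0
07B	paternal	0/0	0.272	0.009	482	5.9e+15	0/0	0/0
38C	paternal	0/0	0.081	0.033	572	2.1e-09	0/1	0/1
49E	paternal	1/1	0.174	0.961	436	2.0e-08	0/1	0/1
38B	paternal	1/1	0.228	0.998	871	4.3e+27	1/1	1/1
52E	paternal	1/1	0.128	0.998	248	4.7e+04	1/1	1/1
17D	paternal	1/1	0.172	0.998	585	1.6e+13	1/1	1/1
18C	paternal	1/1	0.123	0.998	636	3.6e+09	1/1	1/1
52F	paternal	1/1	0.213	0.998	447	5.2e+13	1/1	1/1
04B	paternal	1/1	0.045	0.998	2742	7.1e+09	1/1	1/1
36C	paternal	1/1	0.144	0.998	755	1.4e+14	1/1	1/1
02A	paternal	1/1	0.289	0.998	1497	5.1e+64	1/1	1/1
40B	paternal	1/1	0.237	0.998	988	2.7e+33	1/1	1/1
37A	paternal	1/1	0.209	1.000	2900	1.4e+84	1/1	1/1
30B	recessive	0/1	0.153	0.477	8616	1.0e-44	normal	0/0
31B	recessive	0/1	0.171	0.478	304	1.5e-02	normal	0/0
08A	recessive	0/1	0.134	0.478	2092	3.5e-09	normal	0/0
56C	recessive	0/1	0.325	0.482	663	7.2e-12	normal	0/1
39A	recessive	0/1	0.079	0.498	1868	2.3e-02	normal	0/1
63B	recessive	0/1	0.225	0.505	1386	2.4e-08	normal	0/1
47F	recessive	0/1	0.308	0.508	1319	6.2e-14	normal	0/1
09B	recessive	0/1	0.208	0.521	1601	1.3e-04	normal	0/1
38A	recessive	0/1	0.112	0.568	2328	7.9e+07	affected	1/1
25B	recessive	0/1	0.242	0.569	360	1.7e+01	affected	1/1
40E	recessive	0/1	0.184	0.570	573	2.1e+02	affected	1/1
50C	recessive	0/1	0.179	0.586	1085	3.4e+06	affected	1/1
17B	recessive	0/1	0.219	0.603	1611	1.8e+14	affected	1/1
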