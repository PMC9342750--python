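chromosome	length	centromere_mid	acrocentric
1	248956422	123400000	0
2	242193529	93900000	0
3	198295559	90900000	0
4	190214555	50000000	0
5	181538259	48800000	0
6	170805979	59800000	0
7	159345973	60100000	0
8	145138636	45200000	0
9	138394717	43000000	0
10	133797422	39800000	0
11	135086622	53400000	0
12	133275309	35500000	0
13	114364328	17700000	1
14	107043718	17200000	1
15	101991189	19000000	1
16	90338345	36800000	0
17	83257441	25100000	0
18	80373285	18500000	0
19	58617616	26200000	0
20	64444167	28100000	0
21	46709983	12000000	1
22	50818468	15000000	1
X	156040895	60600000	0
Y	57227415	10400000	0
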