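node	community
1	0
2	0
3	0
4	0
5	0
6	0
7	0
8	0
9	1
10	1
11	0
12	0
13	0
14	0
15	1
16	1
17	0
18	0
19	1
20	0
21	1
22	0
23	1
24	1
25	1
26	1
27	1
28	1
29	1
30	1
31	1
32	1
33	1
34	1
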