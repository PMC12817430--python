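pop_id	lat	lon	sources	allochthonous_sources	admixed	homogeneous_evidence	collector_flag	habitat_years
1	47.45	9.55	Western Europe:admixture_component	Western Europe	1	1	0	2013
2	46.20	7.35	Southern Switzerland:homogeneous		0	0	0
3	46.32	7.95	Southern Switzerland:homogeneous		0	0	0
4	46.95	7.45	Southern Switzerland:homogeneous		0	0	1
5	47.05	8.30	Swiss Plateau:admixture_component;Western Europe:admixture_component;Central Europe:admixture_component	Western Europe;Central Europe	1	0	0
6	46.10	7.08	Southern Switzerland:homogeneous		0	0	0
7	47.38	8.05	Swiss Plateau:homogeneous		0	1	1	1998-2004
8	47.20	7.55	Swiss Plateau:homogeneous		0	1	1
9	47.42	8.55	Swiss Plateau:homogeneous		0	1	1	2002-2005
10	47.10	7.10	Swiss Plateau:homogeneous		0	1	1
11	47.50	8.75	Swiss Plateau:homogeneous		0	1	1	2010-2013
12	47.30	7.95	Swiss Plateau:admixture_component;Western Europe:admixture_component	Western Europe	1	1	1	2016-2019
13	47.55	8.90	Swiss Plateau:homogeneous		0	1	1	2019-2021
14	47.15	8.65	Swiss Plateau:admixture_component;Central Europe:admixture_component	Central Europe	1	1	0
15	47.25	9.10	Swiss Plateau:homogeneous;Central Europe:homogeneous	Central Europe	1	1	0
16	47.48	8.20	Swiss Plateau:homogeneous		0	1	1	2005-2008
17	47.35	7.75	Central Europe:admixture_component;Swiss Plateau:admixture_component;Western Europe:admixture_component	Central Europe;Western Europe	1	0	1	1993-1998
18	47.00	7.25	Swiss Plateau:homogeneous		0	0	0
19	46.85	9.50	Eastern Europe:homogeneous	Eastern Europe	0	1	0
20	46.70	9.85	Eastern Europe:homogeneous	Eastern Europe	0	1	1	2017-2020
21	46.25	7.60	Southern Switzerland:homogeneous		0	0	0
22	46.15	8.80	Southern Switzerland:homogeneous		0	0	0
23	46.40	8.10	Southern Switzerland:homogeneous		0	0	0
24	46.55	8.55	Southern Switzerland:admixture_component;Swiss Plateau:admixture_component		1	0	0
25	47.60	9.20	Central Europe:homogeneous		0	0	0
26	46.50	6.55	Western Europe:homogeneous		0	0	0
27	46.60	6.80	Western Europe:homogeneous		0	0	0
28	46.75	6.95	Western Europe:homogeneous		0	0	0
29	46.90	6.70	Western Europe:homogeneous		0	0	0
30	46.05	7.70	Southern Switzerland:homogeneous		0	0	0
31	46.30	8.45	Southern Switzerland:homogeneous		0	0	0
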