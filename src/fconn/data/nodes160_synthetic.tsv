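node_id	label	x_mm	y_mm	z_mm	network	sphere_radius_mm
0	VN_00	-21.8	-87.3	12.9	VN	5.0
1	VN_01	14.1	-84.4	-3.4	VN	5.0
2	VN_02	7.9	-92.5	8.5	VN	5.0
3	VN_03	35.3	-90.1	18.2	VN	5.0
4	VN_04	13.4	-96.2	0.5	VN	5.0
5	VN_05	30.9	-72.1	-3.6	VN	5.0
6	VN_06	18.7	-91.2	-12.1	VN	5.0
7	VN_07	-27.2	-86.4	1.3	VN	5.0
8	VN_08	-18.7	-67.4	-8.2	VN	5.0
9	VN_09	-29.6	-96.3	5.9	VN	5.0
10	VN_10	28.4	-75.9	17.6	VN	5.0
11	VN_11	18.0	-65.6	17.5	VN	5.0
12	VN_12	3.7	-62.5	2.3	VN	5.0
13	VN_13	-18.1	-81.9	8.3	VN	5.0
14	VN_14	-13.5	-63.9	-6.0	VN	5.0
15	VN_15	-12.8	-89.6	-2.6	VN	5.0
16	VN_16	-39.6	-74.9	-5.1	VN	5.0
17	VN_17	-34.6	-75.3	-8.8	VN	5.0
18	VN_18	-15.6	-82.4	-9.7	VN	5.0
19	VN_19	-22.6	-81.0	1.7	VN	5.0
20	VN_20	-19.6	-88.1	-5.2	VN	5.0
21	VN_21	-19.2	-80.7	-7.6	VN	5.0
22	SMN_00	-0.5	-30.1	61.9	SMN	5.0
23	SMN_01	-38.4	-5.5	28.9	SMN	5.0
24	SMN_02	30.1	-15.6	30.5	SMN	5.0
25	SMN_03	31.2	-30.0	24.3	SMN	5.0
26	SMN_04	14.2	-18.5	51.7	SMN	5.0
27	SMN_05	-39.1	-30.1	54.2	SMN	5.0
28	SMN_06	-50.3	-5.0	41.4	SMN	5.0
29	SMN_07	14.2	-27.5	28.9	SMN	5.0
30	SMN_08	-58.8	-31.6	63.5	SMN	5.0
31	SMN_09	56.7	-22.3	38.9	SMN	5.0
32	SMN_10	-26.9	-1.4	22.9	SMN	5.0
33	SMN_11	-11.0	-33.3	32.0	SMN	5.0
34	SMN_12	33.6	-31.8	47.6	SMN	5.0
35	SMN_13	-16.0	-19.7	36.7	SMN	5.0
36	SMN_14	-26.1	-28.7	24.3	SMN	5.0
37	SMN_15	-2.2	-4.7	67.4	SMN	5.0
38	SMN_16	-56.7	-3.3	26.1	SMN	5.0
39	SMN_17	29.7	-4.1	28.4	SMN	5.0
40	SMN_18	-20.2	-24.9	37.3	SMN	5.0
41	SMN_19	2.0	-39.6	41.1	SMN	5.0
42	SMN_20	45.3	-36.5	44.2	SMN	5.0
43	SMN_21	-2.3	-8.7	68.2	SMN	5.0
44	SMN_22	24.9	-29.1	53.5	SMN	5.0
45	SMN_23	-18.3	-9.3	53.8	SMN	5.0
46	SMN_24	57.3	-5.3	22.3	SMN	5.0
47	SMN_25	-25.2	-5.5	50.0	SMN	5.0
48	SMN_26	-18.7	-37.8	58.1	SMN	5.0
49	SMN_27	-59.8	-36.3	69.7	SMN	5.0
50	SMN_28	33.1	-5.3	43.9	SMN	5.0
51	DAN_00	-33.1	-48.6	42.8	DAN	5.0
52	DAN_01	-33.7	-63.4	37.7	DAN	5.0
53	DAN_02	44.3	-30.5	51.1	DAN	5.0
54	DAN_03	22.3	-40.7	45.5	DAN	5.0
55	DAN_04	-32.3	-34.9	56.4	DAN	5.0
56	DAN_05	21.0	-32.7	59.4	DAN	5.0
57	DAN_06	0.3	-39.7	48.5	DAN	5.0
58	DAN_07	-38.5	-57.4	32.0	DAN	5.0
59	DAN_08	38.7	-69.1	46.1	DAN	5.0
60	DAN_09	-32.2	-64.1	35.0	DAN	5.0
61	DAN_10	37.7	-50.2	40.2	DAN	5.0
62	DAN_11	49.9	-48.2	39.1	DAN	5.0
63	DAN_12	-12.9	-42.2	33.6	DAN	5.0
64	DAN_13	25.8	-34.6	44.3	DAN	5.0
65	VAN_00	-7.5	-13.6	18.3	VAN	5.0
66	VAN_01	31.7	-1.4	29.1	VAN	5.0
67	VAN_02	-54.7	-10.1	6.2	VAN	5.0
68	VAN_03	57.7	-18.0	6.8	VAN	5.0
69	VAN_04	-56.2	8.8	30.9	VAN	5.0
70	VAN_05	-18.5	-18.4	18.9	VAN	5.0
71	VAN_06	-39.4	-0.8	15.5	VAN	5.0
72	VAN_07	-33.5	17.9	33.1	VAN	5.0
73	VAN_08	-3.5	-2.0	1.0	VAN	5.0
74	VAN_09	12.4	2.7	44.8	VAN	5.0
75	VAN_10	56.3	16.4	42.7	VAN	5.0
76	VAN_11	-0.5	-3.2	21.3	VAN	5.0
77	VAN_12	3.7	16.8	3.3	VAN	5.0
78	VAN_13	12.1	20.8	7.2	VAN	5.0
79	VAN_14	-25.5	17.9	30.9	VAN	5.0
80	VAN_15	55.9	8.9	47.2	VAN	5.0
81	SCN_00	19.6	-1.4	-1.2	SCN	5.0
82	SCN_01	-17.2	5.2	1.7	SCN	5.0
83	SCN_02	11.2	-9.8	4.2	SCN	5.0
84	SCN_03	-29.4	3.8	1.2	SCN	5.0
85	SCN_04	-9.8	-22.5	7.5	SCN	5.0
86	SCN_05	16.7	-7.1	4.6	SCN	5.0
87	SCN_06	16.3	-21.6	5.8	SCN	5.0
88	FPN_00	24.9	12.0	50.7	FPN	5.0
89	FPN_01	-4.3	-3.0	54.2	FPN	5.0
90	FPN_02	-4.4	35.2	22.7	FPN	5.0
91	FPN_03	30.9	-0.9	24.4	FPN	5.0
92	FPN_04	-22.4	15.5	37.0	FPN	5.0
93	FPN_05	-7.2	-7.9	40.9	FPN	5.0
94	FPN_06	24.2	48.7	39.4	FPN	5.0
95	FPN_07	43.2	47.1	27.4	FPN	5.0
96	FPN_08	-43.4	0.2	46.1	FPN	5.0
97	FPN_09	-23.9	-3.3	53.0	FPN	5.0
98	FPN_10	18.4	47.5	31.5	FPN	5.0
99	FPN_11	-30.8	-1.8	53.0	FPN	5.0
100	FPN_12	-33.6	38.1	27.4	FPN	5.0
101	FPN_13	36.3	-6.6	33.3	FPN	5.0
102	FPN_14	-9.8	48.6	51.4	FPN	5.0
103	FPN_15	-11.6	15.5	45.0	FPN	5.0
104	FPN_16	14.0	43.6	44.1	FPN	5.0
105	FPN_17	1.5	44.0	31.6	FPN	5.0
106	FPN_18	-13.3	11.1	37.1	FPN	5.0
107	FPN_19	-46.5	17.2	31.1	FPN	5.0
108	FPN_20	-25.7	4.8	47.9	FPN	5.0
109	DMN_00	-12.6	57.4	14.8	DMN	5.0
110	DMN_01	21.7	-33.8	39.6	DMN	5.0
111	DMN_02	-31.6	-37.8	7.6	DMN	5.0
112	DMN_03	-40.8	26.3	15.9	DMN	5.0
113	DMN_04	-41.1	-2.6	19.3	DMN	5.0
114	DMN_05	0.6	21.2	-6.0	DMN	5.0
115	DMN_06	-0.9	-68.0	48.6	DMN	5.0
116	DMN_07	17.6	-52.2	45.2	DMN	5.0
117	DMN_08	-35.8	-27.1	-7.2	DMN	5.0
118	DMN_09	-14.2	23.7	-2.7	DMN	5.0
119	DMN_10	30.5	-17.3	38.1	DMN	5.0
120	DMN_11	-35.9	46.8	33.6	DMN	5.0
121	DMN_12	-49.7	-10.3	-6.1	DMN	5.0
122	DMN_13	24.5	-26.0	36.4	DMN	5.0
123	DMN_14	42.1	-51.2	38.6	DMN	5.0
124	DMN_15	-12.6	-23.4	29.3	DMN	5.0
125	DMN_16	52.2	17.1	3.3	DMN	5.0
126	DMN_17	-55.0	-60.0	7.7	DMN	5.0
127	DMN_18	-47.4	-66.0	46.8	DMN	5.0
128	DMN_19	-38.3	-29.9	47.9	DMN	5.0
129	DMN_20	3.7	18.5	7.3	DMN	5.0
130	DMN_21	18.3	-53.0	10.8	DMN	5.0
131	DMN_22	44.7	23.5	17.7	DMN	5.0
132	DMN_23	-4.6	25.2	13.9	DMN	5.0
133	DMN_24	-7.4	1.6	23.6	DMN	5.0
134	DMN_25	-4.4	6.6	-1.0	DMN	5.0
135	DMN_26	26.3	-53.1	38.5	DMN	5.0
136	DMN_27	8.0	51.3	15.0	DMN	5.0
137	DMN_28	17.4	-65.1	8.2	DMN	5.0
138	DMN_29	-37.2	15.2	-2.7	DMN	5.0
139	DMN_30	-0.2	-40.9	0.1	DMN	5.0
140	DMN_31	34.5	-42.1	-5.2	DMN	5.0
141	DMN_32	-11.8	-46.6	32.8	DMN	5.0
142	CBN_00	9.5	-47.0	-19.5	CBN	5.0
143	CBN_01	-15.5	-50.6	-37.4	CBN	5.0
144	CBN_02	28.3	-79.2	-17.1	CBN	5.0
145	CBN_03	5.2	-66.7	-32.9	CBN	5.0
146	CBN_04	-9.8	-78.7	-26.1	CBN	5.0
147	CBN_05	-11.5	-49.8	-41.3	CBN	5.0
148	CBN_06	-2.6	-61.6	-23.1	CBN	5.0
149	CBN_07	12.4	-67.9	-23.1	CBN	5.0
150	CBN_08	16.8	-69.7	-32.2	CBN	5.0
151	CBN_09	-11.6	-53.9	-40.7	CBN	5.0
152	CBN_10	25.2	-61.5	-33.9	CBN	5.0
153	CBN_11	35.4	-46.7	-15.9	CBN	5.0
154	CBN_12	-31.9	-65.4	-17.4	CBN	5.0
155	CBN_13	-39.3	-73.0	-31.2	CBN	5.0
156	CBN_14	-17.8	-62.1	-28.9	CBN	5.0
157	CBN_15	27.5	-75.4	-22.3	CBN	5.0
158	CBN_16	-0.5	-46.4	-19.3	CBN	5.0
159	CBN_17	-38.4	-69.0	-37.3	CBN	5.0
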