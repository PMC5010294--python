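	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	-1.65	0.98	0.66	1.16	-2.83	1.2	1.8	-0.41	1.9	-3.69	-3.01	0.49	-2.08	-3.73	1.54	-0.08	0.46	0.32	-4.62	-2.31
R	0.98	0.21	1.08	-2.02	-0.41	0.91	-3.13	0.84	0.19	2.05	-0.6	2.34	2.09	-0.4	1.06	0.95	0.98	-5.89	0.36	0.08
N	0.66	1.08	0.61	0.32	-4.18	1.28	0.2	-0.32	1.84	-0.07	0.97	1.12	0.21	0.73	1.15	0.29	0.46	-0.74	0.93	0.93
D	1.16	-2.02	0.32	0.84	-0.82	2.67	1.97	0.88	-1.07	0.68	0.23	-1.93	0.61	-0.92	3.31	0.91	-0.65	-0.71	0.9	0.94
C	-2.83	-0.41	-4.18	-0.82	-39.58	-2.91	-0.53	-2.96	-4.98	0.34	-2.15	-1.38	1.43	-3.07	-2.31	-2.33	-1.84	4.26	-4.46	-0.16
Q	1.2	0.91	1.28	2.67	-2.91	-1.54	0.1	1.11	2.64	-0.18	-0.58	0.43	1.9	0.77	-0.42	1.12	1.65	-2.06	-2.09	0.38
E	1.8	-3.13	0.2	1.97	-0.53	0.1	1.45	1.31	0.61	1.3	1.14	-2.51	2.53	0.94	1.44	0.81	1.54	-1.07	1.29	0.12
G	-0.41	0.84	-0.32	0.88	-2.96	1.11	1.31	-0.2	1.09	-0.65	-0.55	-0.16	-0.52	0.35	2.25	0.71	0.59	1.69	-1.9	-0.38
H	1.9	2.05	1.84	-1.07	-4.98	2.64	0.61	1.09	1.97	-0.71	-0.86	2.89	-0.75	-3.57	0.35	0.82	-0.01	-7.58	-3.2	0.27
I	-3.69	0.19	-0.07	0.68	0.34	-0.18	1.3	-0.65	-0.71	-6.74	-9.01	-0.01	-3.62	-5.88	0.12	-0.15	0.63	-3.78	-5.26	-6.54
L	-3.01	-0.6	0.97	0.23	-2.15	-0.58	1.14	-0.56	-0.86	-9.01	-6.37	0.49	-2.88	-8.59	1.81	-0.41	0.72	-8.31	-4.9	-5.43
K	0.49	2.34	1.12	-1.93	-1.38	0.43	-2.51	-0.16	2.89	-0.01	0.49	1.24	1.61	-0.82	0.51	0.19	-1.11	0.02	-1.19	0.19
M	-2.08	2.09	0.21	0.61	1.43	1.9	2.53	-0.52	-0.75	-3.62	-2.88	1.61	-6.49	-5.34	0.75	1.39	0.63	-6.88	-9.73	-2.59
F	-3.73	-0.4	0.73	-0.92	-3.07	0.77	0.94	0.35	-3.57	-5.88	-8.5	-0.82	-5.34	-11.25	0.32	-2.22	0.11	-7.09	-8.8	-7.05
P	1.54	1.06	1.15	3.31	-2.13	2.97	1.44	2.25	0.35	0.12	1.81	0.51	0.75	0.32	-0.42	1.12	1.65	-2.06	-2.09	0.38
S	-0.08	0.95	0.29	0.91	-2.33	0.85	0.81	0.71	0.82	-0.15	-0.41	0.19	1.39	-2.22	1.12	-0.48	-0.06	-3.03	-0.82	0.13
T	0.46	0.98	0.46	-0.65	-1.84	-0.07	1.54	0.59	-0.01	0.63	0.72	-1.11	0.63	0.11	1.65	-0.06	-0.96	-0.65	-0.37	1.14
W	0.32	-5.89	-0.74	-0.71	4.26	-0.76	-1.07	1.69	-7.58	-3.78	-8.31	0.02	-6.88	-7.09	-2.06	-3.03	-0.65	-1.73	-12.39	-2.13
Y	-4.62	0.36	0.93	0.9	-4.46	0.01	1.29	-1.9	-3.2	-5.26	-4.9	-1.19	-9.73	-8.8	-2.09	-0.37	-0.37	-12.39	-2.68	-3.59
V	-2.31	0.08	0.93	0.94	-0.16	-1.91	0.12	-0.38	0.27	-6.54	-5.43	0.19	-2.59	-7.05	0.38	0.13	1.14	-2.13	-3.59	-4.82
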