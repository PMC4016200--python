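family	transcript_id	root_1h	root_24h	shoot_1h	shoot_24h	root_1h_bold	root_24h_bold	shoot_1h_bold	shoot_24h_bold
HMA	Os02t0585200-01	10.78	87.00	0.27	2.11	1	1	0	0
HMA	Os03t0152000-01	7.68	34.42	0.09	0.91	1	1	0	0
HMA	Os02t0584800-01	3.15	33.27	0.15	0.78	0	1	0	0
HMA	Os02t0585100-00	5.67	23.19	1.03	5.24	1	1	0	1
HMA	Os02t0584700-01	3.32	17.49	0.23	1.09	0	1	0	0
HMA	Os03t0372600-00	2.48	9.90	1.21	2.41	0	1	0	0
HMA	Os02t0530100-02	0.98	7.17	0.55	0.42	0	1	0	0
HMA	Os02t0530100-01	0.92	7.03	0.56	0.45	0	1	0	0
HMA	Os01t0976300-01	3.07	6.36	0.96	13.77	0	1	0	1
HMA	Os04t0244800-01	5.67	3.67	1.95	5.61	1	0	0	1
HMA	Os06t0542300-01	1.39	2.35	0.62	15.21	0	0	0	1
HMA	Os06t0665800-01	1.06	2.33	1.51	5.90	0	0	0	1
HMA	Os08t0403300-00	0.49	1.73	1.07	6.41	0	0	0	1
HMA	Os03t0178100-00	1.10	0.67	1.85	5.25	0	0	0	1
MatE	Os10t0344000-01	1.05	12.19	0.63	13.65	0	1	0	1
MatE	Os03t0188100-01	1.75	9.77	1.22	14.48	0	1	0	1
MatE	Os10t0345100-01	2.63	4.53	2.04	6.69	0	0	0	1
MatE	Os04t0571600-01	10.32	2.55	1.13	0.25	1	0	0	0
MatE	Os03t0572900-01	1.18	0.97	1.45	7.38	0	0	0	1
MatE	Os07t0502200-01	2.45	1.30	2.65	6.24	0	0	0	1
MatE	Os01t0504500-02	0.97	0.90	1.10	5.39	0	0	0	1
MatE	Os02t0676400-00	7.77	0.73	1.12	1.13	1	0	0	0
Zip	Os03t0411800-01	1.21	10.56	1.20	14.60	0	1	0	1
Zip	Os01t0972200-00	5.06	1.69	1.39	2.07	1	0	0	0
Cation_efflux	Os01t0130000-01	1.45	1.02	1.46	6.70	0	0	0	1
Cation_efflux	Os01t0130000-02	1.28	0.92	1.30	5.82	0	0	0	1
Nramp	Os07t0258400-02	0.66	5.05	1.08	1.50	0	1	0	0
PDR_assoc	Os01t0342750-01	0.75	5.82	0.91	2.47	0	1	0	0
PDR_assoc	CUFF.28142.2	2.97	2.43	2.47	45.91	0	0	0	1
PDR_assoc	Os01t0609900-02	1.75	2.14	1.77	53.64	0	0	0	1
PDR_assoc	Os01t0609300-01	1.55	2.03	1.03	32.64	0	0	0	1
PDR_assoc	Os08t0384500-01	1.51	1.30	1.59	5.20	0	0	0	1
PDR_assoc	Os01t0609200-00	6.67	0.74	1.04	1.15	1	0	0	0
LCT1	CUFF.25087.1	1.11	1.57	1.87	5.65	0	0	0	1
LCT1	CUFF.25087.2	1.08	1.48	1.96	6.04	0	0	0	1
LCT1	CUFF.25087.3	1.12	1.49	1.95	5.97	0	0	0	1
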