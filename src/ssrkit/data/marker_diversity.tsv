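marker	n_alleles	ho	gd	pic
Evg-01	9	0.64	0.67	0.63
Evg-02	8	0.70	0.75	0.72
Evg-03	6	0.64	0.64	0.58
Evg-04	9	0.87	0.77	0.73
Evg-05	4	0.49	0.65	0.58
Evg-06	3	0.37	0.52	0.41
Evg-07	6	0.82	0.72	0.67
Evg-08	11	0.42	0.79	0.77
Evg-09	9	0.83	0.79	0.76
Evg-10	8	0.49	0.73	0.70
Evg-11	6	0.78	0.66	0.62
Evg-12	12	0.78	0.75	0.72
Evg-13	7	0.58	0.60	0.52
Evg-14	3	0.96	0.52	0.41
Evg-15	5	0.41	0.68	0.62
Evg-16	3	0.21	0.23	0.20
Evg-17	8	0.72	0.72	0.68
Evg-18	4	0.69	0.66	0.60
Evg-19	5	0.13	0.12	0.12
Evg-20	6	0.24	0.71	0.67
Evg-21	5	0.79	0.69	0.65
Evg-22	4	0.74	0.63	0.57
Evg-23	6	0.57	0.64	0.59
Evg-24	4	0.10	0.25	0.24
Evg-25	5	0.58	0.60	0.53
Evg-26	6	0.80	0.68	0.64
Evg-27	8	0.40	0.66	0.61
Evg-28	4	0.59	0.59	0.51
Evg-29	5	0.51	0.60	0.55
Evg-48	3	0.70	0.59	0.51
Evg-49	4	0.10	0.10	0.09
Evg-50	5	0.29	0.27	0.25
Evg-51	2	0.32	0.50	0.37
Evg-52	9	0.44	0.62	0.55
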