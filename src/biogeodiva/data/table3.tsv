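# Cladogenetic events, candidate geological/biotic windows (Ma), and the
# 95% node-age intervals from the three dating analyses.  Windows are
# transcribed bounds-as-printed with older_Ma >= younger_Ma after
# normalisation (the Hitchhiking window is printed younger-first).
cladogenetic_event	geological_event	kind	older_Ma	younger_Ma	B1_lower	B1_upper	B2_lower	B2_upper	B3_lower	B3_upper	recorded_decision
R. pallescens / (R. ecuadoriensis + R. colombiensis)	Panama isthmus	geological	10.1	2.76	0.64	11.75	0.66	11.59	0.61	12.65	not_rejected
R. pallescens / (R. ecuadoriensis + R. colombiensis)	last Andean uplift (Pliocene)	geological	5.3	2.6	0.64	11.75	0.66	11.59	0.61	12.65	not_rejected
pallescens group / (pictipes group + prolixus group)	Pebas System	geological	23	10	12.33	30.53	17.76	34.16	18.15	34.86	not_rejected
pictipes group / prolixus group	Pebas System	geological	23	10	9.41	22.94	12.77	25.62	13.16	26.69	not_rejected
R. neivai / R. domesticus	Acre System	geological	10.0	7.0	5.46	16.01	6.48	17.88	6.56	18.49	not_rejected
venosa clade / other Triatomini	Western Cordillera Uplift	geological	55	25	22.23	39	26.25	41.75	23.96	37.99	not_rejected
T. venosa / Triatoma sp.2	last Andean uplift (Pliocene)	geological	5.3	2.6	1.6	13.14	2.19	14.54	2.22	15.42	not_rejected
T. maculata / infestans group	Pebas System	geological	23	10	9.51	20.88	14.76	28.37	8.83	18.27	not_rejected
T. maculata / infestans group	Acre System	geological	10.0	7.0	9.51	20.88	14.76	28.37	8.83	18.27	rejected
T. bruneri / megistus group	Hitchhiking	biotic	18.2	14.8	8.14	19.72	9.29	22.29	9.22	23.16	not_rejected
T. bruneri / megistus group	GAARlandia	geological	35	33	8.14	19.72	9.29	22.29	9.22	23.16	rejected
T. tibiamaculata / P. megistus	old AF/Am pathway	geological	23	5.3	2.92	13.8	3.01	13.87	2.77	14.81	not_rejected
(Linshcosteus sp. + T. rubrofasciata) / phyllosoma group	Bering land bridge	geological	25	10	11.92	31.64	16.71	28.34	14.18	26.05	not_rejected
T. sanguisuga / phyllosoma group (part)	high sea level in early Miocene	geological	11.6	5.3	5.94	15.59	8.41	19.73	6.87	16.9	not_rejected
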