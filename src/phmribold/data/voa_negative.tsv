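region	veh	mg_1_0	mg_3_3	mg_10	p	omega_sq
Medial geniculate	0	11	0	0	0	0.524
Zona incerta	0	6	0	0	0.001	0.475
Habenular area	0	2	4	0	0.001	0.498
Caudal piriform ctx	5	61	31	37	0.002	0.409
Anterior pretectal thalamic area	0	6	3	0	0.002	0.434
Insular caudal ctx	0	24	13	2	0.002	0.409
Caudate putamen	0	86	39	48	0.002	0.427
External capsule	0	3	1	4	0.003	0.397
Medullary reticular ventral area	1	17	23	21	0.004	0.392
Second cerebellar lobule	0	11	17	1	0.005	0.351
Third cerebellar lobule	0	5	1	0	0.006	0.343
Bed n. stria terminalis	0	4	3	0	0.006	0.366
Medial dorsal thalamic area	0	5	6	0	0.006	0.378
Tenth cerebellar lobule	0	2	4	0	0.006	0.366
Corpus callosum	0	14	5	3	0.008	0.321
Anterior thalamic area	0	6	16	0	0.008	0.347
Anterior hypothalamic area	0	10	25	13	0.009	0.328
Lateral caudal hypothalamic area	0	3	0	3	0.01	0.269
Superior colliculus	0	29	7	2	0.01	0.291
Principal sensory n. trigeminal	0	14	8	3	0.011	0.313
Cerebral peduncle	0	12	17	2	0.012	0.316
Auditory ctx	0	12	10	1	0.012	0.325
Lateral rostral hypothalamic area	0	6	0	2	0.013	0.288
Entorhinal ctx	11	80	85	44	0.013	0.316
Lateral septal area	0	20	17	10	0.014	0.314
Basal amygdaloid area	0	10	4	27	0.015	0.286
Rostral piriform ctx	5	69	57	32	0.015	0.274
Lateral paragigantocellular area	0	8	14	13	0.015	0.260
Central amygdaloid area	0	6	0	4	0.015	0.287
Medial preoptic area	0	3	14	11	0.016	0.278
Cortical amygdaloid area	5	41	37	31	0.016	0.270
Central medial thalamic area	0	0	0	0	0.018	0.212
Inferior colliculus	0	29	1	0	0.018	0.215
Paraventricular thalamic area	0	0	7	0	0.019	0.281
Endopiriform area	0	7	0	0	0.019	0.246
Reticular thalamic area	0	5	1	0	0.022	0.246
CA3	2	33	22	4	0.022	0.254
CA1	1	42	37	5	0.025	0.241
Cerebellar nuclear area	0	2	4	1	0.025	0.258
Flocculus cerebellum	5	23	22	22	0.025	0.248
Olivary complex	0	8	0	8	0.027	0.200
Fifth cerebellar lobule	0	10	9	0	0.028	0.231
Olfactory tubercles	0	7	13	11	0.028	0.228
Pontine reticular nucleus oral	0	11	1	2	0.029	0.220
Posterior hypothalamic area	0	0	0	2	0.031	0.137
Vestibular area	0	11	18	0	0.032	0.225
Anterior commissure	0	1	0	0	0.038	0.231
Periaqueductal gray	0	35	11	0	0.041	0.165
Accumbens core	0	11	1	0	0.042	0.238
Lateral geniculate	0	1	1	0	0.044	0.224
Gigantocellaris reticular area	3	11	24	27	0.046	0.221
Dorsal raphe	0	0	2	3	0.048	0.191
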