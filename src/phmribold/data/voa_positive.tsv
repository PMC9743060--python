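region	veh	mg_1_0	mg_3_3	mg_10	p	omega_sq
Auditory ctx	0	20	39	4	0.002	0.483
Lateral lemniscus	0	14	0	9	0.002	0.467
Primary somatosensory ctx	12	164	136	8	0.003	0.434
Paramedian lobule	1	16	4	37	0.003	0.420
Pontine area	0	32	2	37	0.003	0.416
Gigantocellaris reticular area	0	26	0	39	0.003	0.416
Entorhinal ctx	27	151	75	115	0.004	0.410
Cerebral peduncle	0	46	8	19	0.005	0.393
Lateral septal area	0	18	4	0	0.005	0.392
Secondary somatosensory ctx	4	45	27	0	0.005	0.386
Secondary motor ctx	1	23	10	0	0.007	0.362
Habenular area	0	3	0	0	0.007	0.354
Primary motor ctx	2	34	15	0	0.008	0.342
Lateral dorsal thalamic area	0	6	1	0	0.008	0.342
Ventral medial hypothalamic area	0	5	0	8	0.009	0.337
7th cerebellar lobule	0	1	0	9	0.009	0.337
Subiculum	0	16	9	32	0.009	0.335
Principal sensory n. trigeminal	0	25	5	26	0.009	0.333
Glomerular layer	0	26	6	7	0.01	0.328
Prepositus area	0	1	0	0	0.011	0.314
Frontal association ctx	0	22	11	1	0.012	0.308
Lateral posterior thalamic area	0	1	0	0	0.014	0.299
Parvicellular reticular area	0	11	1	18	0.015	0.293
Medial dorsal thalamic area	0	4	0	0	0.015	0.289
Posterior thalamic area	0	4	0	0	0.016	0.284
Parafascicular thalamic area	0	0	0	0	0.018	0.278
Anterior thalamic area	0	11	2	0	0.018	0.277
Central amygdaloid area	0	3	7	0	0.019	0.271
Central medial thalamic area	0	1	0	0	0.02	0.265
Flocculus cerebellum	6	46	44	52	0.021	0.261
Fimbria hippocampus	4	18	9	0	0.022	0.259
Ventral pallidum	0	6	0	1	0.022	0.257
Accumbens shell	0	2	0	0	0.024	0.250
Lateral geniculate	0	0	3	0	0.026	0.245
Tenia tecta ctx	2	14	0	5	0.026	0.243
Caudate putamen	12	93	45	0	0.026	0.243
Ventral thalamic area	0	40	26	4	0.028	0.237
Spinal trigeminal nuclear area	8	52	12	35	0.029	0.234
Anterior hypothalamic area	0	19	1	16	0.031	0.230
Intermediate reticular area	1	9	1	12	0.031	0.229
Lateral rostral hypothalamic area	0	8	5	4	0.032	0.227
CA3	2	36	12	3	0.032	0.226
Insular rostral ctx	21	38	50	4	0.036	0.215
Dorsal medial hypothalamic area	0	4	0	2	0.04	0.208
Lateral amygdaloid area	0	0	2	0	0.04	0.207
Prelimbic ctx	0	6	0	0	0.041	0.038
Basal amygdaloid area	0	22	3	9	0.041	0.204
Pituitary	1	9	0	7	0.043	0.201
Medial preoptic area	0	12	0	4	0.044	0.198
CA1	2	57	31	5	0.046	0.194
Pontine reticular nucleus caudal	3	16	3	25	0.047	0.193
Facial nucleus	0	3	0	4	0.048	0.191
Orbital ctx	0	10	10	0	0.048	0.191
Pontine reticular nucleus oral	1	20	2	11	0.048	0.190
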