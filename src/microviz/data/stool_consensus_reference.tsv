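otu_id	score	methods	mean_pct_tp2	sd_tp2	mean_pct_tp3	sd_tp3	taxonomy
32	3	MEV	0.049	0.030	0.000	0.000	Bacteria1.0Firmicutes0.66Clostridia0.64Clostridiales0.64Ruminococcaceae0.48Faecalibacterium0.44
89	3	MEV	3.635	2.869	0.056	0.097	Bacteria1.0Firmicutes0.98Clostridia0.98Clostridiales0.98Lachnospiraceae0.9Pseudobutyrivibrio0.36
95	3	MEV	0.086	0.055	0.000	0.000	Bacteria1.0Firmicutes0.99Clostridia0.99Clostridiales0.99Lachnospiraceae0.97Dorea0.54
144	3	MEV	0.148	0.163	0.000	0.000	Bacteria1.0Firmicutes0.99Clostridia0.99Clostridiales0.99Lachnospiraceae0.99Lachnospira0.79
194	3	MEV	2.529	1.296	0.080	0.100	Bacteria1.0Bacteroidetes1.0Bacteroidetes1.0Bacteroidales1.0Rikenellaceae1.0Alistipes1.0
246	3	MEV	0.056	0.021	0.001	0.002	Bacteria1.0Firmicutes0.56Clostridia0.52Clostridiales0.33Lachnospiraceae0.16Sporobacterium0.02
338	3	MEV	0.065	0.069	0.000	0.000	Bacteria1.0Firmicutes0.98Clostridia0.98Clostridiales0.98Lachnospiraceae0.98Roseburia0.95
466	3	MEV	0.135	0.131	0.002	0.004	Bacteria1.0Firmicutes0.75Clostridia0.69Clostridiales0.66Ruminococcaceae0.47Ethanoligenens0.37
783	3	MEV	0.074	0.065	0.000	0.000	Bacteria1.0Firmicutes0.84Clostridia0.83Clostridiales0.83Ruminococcaceae0.52Sporobacter0.17
1005	3	MEV	0.217	0.158	0.002	0.004	Bacteria0.99Bacteroidetes0.97Bacteroidetes0.67Bacteroidales0.67Rikenellaceae0.67Alistipes0.67
1171	3	MEV	0.372	0.235	0.007	0.010	Bacteria1.0Proteobacteria0.52Alphaproteobacteria0.3Sphingomonadales0.14Sphingomonadaceae0.14Sphingosinicella0.12
1660	3	MEV	0.068	0.060	0.000	0.000	Bacteria0.99Bacteroidetes0.97Bacteroidetes0.49Bacteroidales0.49Bacteroidaceae0.31Bacteroides0.31
2361	3	MEV	0.118	0.121	0.000	0.000	Bacteria1.0Firmicutes0.74Clostridia0.74Clostridiales0.74Ruminococcaceae0.58Faecalibacterium0.41
1472	2	MV	0.139	0.092	0.034	0.068	Bacteria1.0Firmicutes0.66Clostridia0.64Clostridiales0.64Ruminococcaceae0.42Faecalibacterium0.38
9	2	MV	0.012	0.019	0.210	0.174	Bacteria1.0Firmicutes1.0Clostridia1.0Clostridiales1.0Ruminococcaceae1.0Faecalibacterium1.0
13	2	MV	4.401	3.270	16.617	12.017	Bacteria1.0Bacteroidetes1.0Bacteroidetes0.99Bacteroidales0.99Bacteroidaceae0.99Bacteroides0.99
16	2	ME	0.000	0.000	0.021	0.011	Bacteria1.0Firmicutes1.0Bacilli1.0Lactobacillales1.0Leuconostocaceae0.91Weissella0.9
21	2	MV	0.018	0.007	0.073	0.034	Bacteria1.0Firmicutes0.87Clostridia0.86Clostridiales0.86Lachnospiraceae0.86Roseburia0.78
41	2	MV	0.123	0.110	0.891	0.449	Bacteria1.0Firmicutes1.0Clostridia1.0Clostridiales1.0Ruminococcaceae1.0Faecalibacterium1.0
66	2	MV	0.052	0.027	0.531	0.263	Bacteria1.0Firmicutes0.98Clostridia0.98Clostridiales0.98Lachnospiraceae0.98Roseburia0.38
74	2	MV	0.093	0.118	0.322	0.127	Bacteria1.0Firmicutes0.92Erysipelotrichi0.89Erysipelotrichales0.89Erysipelotrichaceae0.89Coprobacillus0.78
92	2	EV	0.613	1.203	0.000	0.000	Bacteria0.99Firmicutes0.54Clostridia0.49Clostridiales0.48Incertae Sedis XV0.24Aminobacterium0.22
108	2	MV	0.019	0.020	0.113	0.050	Bacteria1.0Firmicutes0.97Clostridia0.97Clostridiales0.96Lachnospiraceae0.9Roseburia0.57
206	2	MV	0.178	0.148	0.773	0.383	Bacteria1.0Firmicutes0.97Clostridia0.97Clostridiales0.97Ruminococcaceae0.97Faecalibacterium0.96
215	2	MV	0.110	0.094	0.595	0.314	Bacteria1.0Firmicutes0.99Clostridia0.99Clostridiales0.99Lachnospiraceae0.94Lachnospiraceae Incertae Sedis0.35
222	2	MV	0.386	0.153	0.024	0.028	Bacteria0.99Bacteroidetes0.95Bacteroidetes0.56Bacteroidales0.56Bacteroidaceae0.38Bacteroides0.38
343	2	MV	0.049	0.049	0.002	0.004	Bacteria1.0Firmicutes0.99Clostridia0.97Clostridiales0.97Ruminococcaceae0.94Ruminococcus0.93
479	2	MV	0.154	0.144	0.004	0.004	Bacteria1.0Bacteroidetes0.97Flavobacteria0.65Flavobacteriales0.65Cryomorphaceae0.27Fluviicola0.22
501	2	MV	0.091	0.105	0.347	0.206	Bacteria0.98Firmicutes0.84Clostridia0.84Clostridiales0.84Lachnospiraceae0.76Syntrophococcus0.64
534	2	MV	0.309	0.499	1.402	0.483	Bacteria1.0Firmicutes0.96Clostridia0.95Clostridiales0.95Lachnospiraceae0.93Lachnobacterium0.29
561	2	MV	0.380	0.205	0.073	0.078	Bacteria1.0Bacteroidetes1.0Bacteroidetes1.0Bacteroidales1.0Rikenellaceae1.0Alistipes1.0
654	2	MV	0.077	0.076	0.004	0.009	Bacteria1.0Bacteroidetes1.0Bacteroidetes1.0Bacteroidales1.0Rikenellaceae1.0Alistipes1.0
1156	2	ME	0.072	0.071	0.000	0.000	Bacteria1.0Firmicutes1.0Clostridia1.0Clostridiales1.0Ruminococcaceae1.0Acetanaerobacterium0.66
1732	2	ME	0.045	0.031	0.000	0.000	Bacteria1.0Firmicutes0.76Clostridia0.72Clostridiales0.71Incertae Sedis XIII0.29Anaerovorax0.29
1861	2	MV	0.412	0.379	0.028	0.044	Bacteria1.0Bacteroidetes1.0Bacteroidetes1.0Bacteroidales1.0Rikenellaceae1.0Alistipes1.0
1959	2	ME	0.019	0.016	0.000	0.000	Bacteria1.0Firmicutes0.95Clostridia0.95Clostridiales0.95Ruminococcaceae0.5Faecalibacterium0.23
1983	2	EV	0.127	0.170	0.000	0.000	Bacteria1.0Firmicutes0.84Clostridia0.83Clostridiales0.83Ruminococcaceae0.72Faecalibacterium0.44
2034	2	EV	0.081	0.097	0.000	0.000	Bacteria1.0Firmicutes0.68Clostridia0.66Clostridiales0.63Ruminococcaceae0.54Faecalibacterium0.38
3402	2	MV	0.071	0.071	0.001	0.002	Bacteria1.0Firmicutes0.61Clostridia0.6Clostridiales0.6Peptococcaceae0.51Peptococcus0.51
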