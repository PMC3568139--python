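otu_id	score	methods	mean_pct_tp2	sd_tp2	mean_pct_tp3	sd_tp3	taxonomy
1341	3	MEV	0.000	0.000	0.062	0.035	Bacteria1.0Proteobacteria1.0Gammaproteobacteria1.0Pseudomonadales0.99Pseudomonadaceae0.99Pseudomonas0.67
11	2	MV	2.292	1.527	4.509	0.841	Bacteria1.0Firmicutes0.99Bacilli0.99Lactobacillales0.99Streptococcaceae0.98Lactococcus0.9
13	2	EV	7.117	10.403	0.214	0.319	Bacteria1.0Bacteroidetes1.0Bacteroidetes0.99Bacteroidales0.99Bacteroidaceae0.99Bacteroides0.99
25	2	ME	0.034	0.023	0.000	0.000	Bacteria1.0Firmicutes0.98Clostridia0.98Clostridiales0.98Lachnospiraceae0.96Dorea0.26
27	2	EV	1.720	2.409	0.039	0.061	Bacteria1.0Bacteroidetes1.0Bacteroidetes1.0Bacteroidales1.0Bacteroidaceae1.0Bacteroides1.0
42	2	EV	0.347	0.472	0.019	0.033	Bacteria1.0Firmicutes1.0Clostridia1.0Clostridiales1.0Ruminococcaceae1.0Faecalibacterium1.0
44	2	MV	0.187	0.112	1.069	0.706	Bacteria1.0Proteobacteria1.0Gammaproteobacteria1.0Pseudomonadales0.93Moraxellaceae0.75Acinetobacter0.73
48	2	MV	0.169	0.084	0.051	0.058	Bacteria1.0Bacteroidetes1.0Bacteroidetes1.0Bacteroidales1.0Bacteroidaceae1.0Bacteroides1.0
51	2	MV	0.076	0.043	0.147	0.020	Bacteria1.0Firmicutes0.98Bacilli0.98Lactobacillales0.98Leuconostocaceae0.97Weissella0.97
85	2	EV	0.129	0.116	0.000	0.000	Bacteria1.0Bacteroidetes0.97Bacteroidetes0.97Bacteroidales0.97Bacteroidaceae0.95Bacteroides0.95
89	2	EV	0.243	0.258	0.000	0.000	Bacteria1.0Firmicutes0.98Clostridia0.98Clostridiales0.98Lachnospiraceae0.9Pseudobutyrivibrio0.36
94	2	EV	1.489	1.443	0.040	0.069	Bacteria1.0Bacteroidetes0.99Bacteroidetes0.99Bacteroidales0.99Bacteroidaceae0.99Bacteroides0.99
101	2	MV	0.023	0.030	0.090	0.018	Bacteria1.0Proteobacteria1.0Gammaproteobacteria1.0Pseudomonadales0.93Moraxellaceae0.9Acinetobacter0.9
115	2	MV	0.857	0.548	1.711	0.161	Bacteria1.0Firmicutes0.99Bacilli0.99Lactobacillales0.99Streptococcaceae0.98Lactococcus0.98
145	2	EV	1.222	2.022	0.004	0.006	Bacteria1.0Bacteroidetes0.97Bacteroidetes0.97Bacteroidales0.97Bacteroidaceae0.97Bacteroides0.97
150	2	EV	0.385	0.348	0.000	0.000	Bacteria1.0Bacteroidetes0.99Bacteroidetes0.98Bacteroidales0.98Bacteroidaceae0.95Bacteroides0.95
158	2	MV	0.131	0.105	0.354	0.168	Bacteria1.0Proteobacteria1.0Betaproteobacteria1.0Burkholderiales1.0Comamonadaceae0.99Acidovorax0.88
177	2	EV	1.876	2.951	0.000	0.000	Bacteria1.0Bacteroidetes1.0Bacteroidetes1.0Bacteroidales1.0Porphyromonadaceae1.0Parabacteroides1.0
194	2	EV	0.225	0.276	0.000	0.000	Bacteria1.0Bacteroidetes1.0Bacteroidetes1.0Bacteroidales1.0Rikenellaceae1.0Alistipes1.0
212	2	MV	0.717	0.490	1.415	0.189	Bacteria1.0Firmicutes1.0Bacilli1.0Lactobacillales1.0Streptococcaceae1.0Streptococcus1.0
243	2	EV	0.101	0.097	0.000	0.000	Bacteria1.0Firmicutes0.7Clostridia0.68Clostridiales0.67Ruminococcaceae0.28Faecalibacterium0.23
284	2	MV	0.025	0.011	0.098	0.016	Bacteria1.0Proteobacteria1.0Gammaproteobacteria0.98Pseudomonadales0.9Moraxellaceae0.66Acinetobacter0.65
596	2	ME	0.000	0.000	0.022	0.019	Bacteria1.0Proteobacteria1.0Epsilonproteobacteria1.0Campylobacterales1.0Campylobacteraceae1.0Arcobacter1.0
666	2	EV	0.090	0.084	0.000	0.000	Bacteria1.0Firmicutes0.97Clostridia0.96Clostridiales0.96Lachnospiraceae0.94Dorea0.35
681	2	MV	0.094	0.044	0.163	0.025	Bacteria1.0Firmicutes0.98Bacilli0.98Lactobacillales0.97Streptococcaceae0.97Lactococcus0.92
693	2	MV	0.052	0.060	0.184	0.020	Bacteria1.0Proteobacteria1.0Epsilonproteobacteria1.0Campylobacterales0.96Campylobacteraceae0.94Sulfurospirillum0.91
791	2	MV	0.027	0.014	0.082	0.031	Bacteria1.0Firmicutes0.98Bacilli0.97Lactobacillales0.97Streptococcaceae0.97Lactococcus0.97
828	2	MV	0.052	0.033	0.120	0.009	Bacteria1.0Firmicutes0.97Bacilli0.96Lactobacillales0.96Streptococcaceae0.94Lactococcus0.94
901	2	ME	0.018	0.012	0.000	0.000	Bacteria1.0Proteobacteria0.95Betaproteobacteria0.86Burkholderiales0.65Oxalobacteraceae0.4Naxibacter0.34
902	2	ME	0.014	0.006	0.000	0.000	Bacteria1.0Proteobacteria1.0Betaproteobacteria1.0Burkholderiales1.0Incertae sedis 50.87Pelomonas0.82
911	2	ME	0.029	0.014	0.000	0.000	Bacteria1.0Bacteroidetes1.0Bacteroidetes1.0Bacteroidales1.0Bacteroidaceae1.0Bacteroides1.0
953	2	MV	0.038	0.023	0.118	0.066	Bacteria1.0Proteobacteria1.0Betaproteobacteria1.0Burkholderiales1.0Comamonadaceae1.0Acidovorax0.82
987	2	ME	0.014	0.010	0.000	0.000	Bacteria1.0Firmicutes1.0Clostridia1.0Clostridiales1.0Ruminococcaceae1.0Faecalibacterium1.0
1057	2	EV	0.064	0.064	0.000	0.000	Bacteria1.0Bacteroidetes0.98Bacteroidetes0.98Bacteroidales0.98Bacteroidaceae0.98Bacteroides0.98
1257	2	EV	0.128	0.163	0.000	0.000	Bacteria1.0Firmicutes0.93Clostridia0.93Clostridiales0.93Ruminococcaceae0.91Subdoligranulum0.61
1391	2	ME	0.006	0.004	0.000	0.000	Bacteria1.0Firmicutes0.99Bacilli0.99Lactobacillales0.99Leuconostocaceae0.93Weissella0.93
1477	2	MV	0.030	0.025	0.080	0.013	Bacteria1.0Firmicutes0.98Bacilli0.97Lactobacillales0.97Leuconostocaceae0.82Weissella0.81
1497	2	MV	0.020	0.019	0.080	0.033	Bacteria1.0Proteobacteria1.0Gammaproteobacteria1.0Pseudomonadales0.9Moraxellaceae0.9Acinetobacter0.9
1690	2	MV	0.034	0.043	0.120	0.057	Bacteria1.0Proteobacteria1.0Gammaproteobacteria1.0Enterobacteriales1.0Enterobacteriaceae1.0Raoultella0.28
1834	2	MV	0.084	0.066	0.247	0.119	Bacteria1.0TM70.53TM7_genera_incertae_sedis0.53
1993	2	MV	0.033	0.038	0.109	0.041	Bacteria1.0Bacteroidetes1.0Flavobacteria1.0Flavobacteriales1.0Flavobacteriaceae1.0Chryseobacterium0.79
2062	2	ME	0.008	0.006	0.000	0.000	Bacteria1.0Bacteroidetes0.97Bacteroidetes0.94Bacteroidales0.94Bacteroidaceae0.93Bacteroides0.93
2156	2	ME	0.022	0.006	0.001	0.002	Bacteria1.0Bacteroidetes0.99Bacteroidetes0.98Bacteroidales0.98Bacteroidaceae0.97Bacteroides0.97
2229	2	MV	0.025	0.021	0.087	0.018	Bacteria1.0Firmicutes0.98Bacilli0.97Lactobacillales0.97Leuconostocaceae0.94Weissella0.94
6041	2	ME	0.008	0.004	0.000	0.000	Bacteria1.0Proteobacteria0.98Betaproteobacteria0.97Burkholderiales0.9Incertae sedis 50.48Leptothrix0.26
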