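cell_name	compound_id	compound_name	dose_um	time_h	n_signature_genes	transcriptional_activity	mechanism	targets	raw_score	normalized_score	fdr_q
JURKAT	BRD-A33746814	avicin-g	0.37	24	482	0.5	NFKB inhibitor	NA	-0.4	-1.51	4.47e-16
THP1	BRD-K12683773	methyl-fasudil	10	6	252	0.4	NA	NA	-0.43	-1.65	2.24e-16
BJAB	BRD-K03390685	cobimetinib	10	4	214	0.33	MEK inhibitor	NA	-0.4	-1.52	2.24e-16
THP1	BRD-K32330832	VER-155,008	12	6	86	0.12	HSP inhibitor	HSPA1A	-0.38	-1.44	0.0339
JURKAT	BRD-A49838158	phenprocoumon	0.03	24	77	0.1	Vitamin K antagonist	VKORC1	-0.38	-1.45	0.0302
K562	BRD-K32972437	BRD-K32972437	10	4	76	0.12	NA	NA	-0.38	-1.45	0.0302
NALM6	BRD-K20285085	fostamatinib	10	24	275	0.37	Syk inhibitor	NA	-0.39	-1.46	0.0195
THP1	BRD-K65170927	aprepitant	0.37	24	195	0.11	Tachykinin antagonist	TACR1|CYP2C19	-0.39	-1.47	0.0186
JURKAT	BRD-K42495768	tasisulam	0.01	24	126	0.18	Apoptosis stimulant	NA	-0.39	-1.47	0.0151
JURKAT	BRD-A45498368	WYE-125,132	1.11	24	568	1.08	MTOR inhibitor	MTOR|PIK3CA	-0.39	-1.5	0.0041
THP1	BRD-K68392338	ZK-93,426	0.04	24	96	0.11	Benzodiazepine receptor antagonist	GABRA1|GABRA2|GABRA3|GABRA5	-0.4	-1.5	0.0019
THP1	BRD-K12423485	griseofulvin	10	24	220	0.18	Tubulin inhibitor	KRT12	-0.4	-1.5	0.0014
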