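mirna_id	direction	raw_mean_minus80	raw_sem_minus80	raw_mean_minus20	raw_sem_minus20	log2cpm_mean_minus80	log2cpm_sem_minus80	log2cpm_mean_minus20	log2cpm_sem_minus20	kidney_disease_annotation
hsa-miR-21-5p	down	42760	22321	230	115	14.5	0.4	12.1	0.4	Dysregulated in DKD in human tissue and DKD models
hsa-miR-375	down	11496	4880	26	13	12.9	0.1	7.3	2	Pro-apoptotic in an in vitro model of AKI (renal tubular cells)
hsa-miR-192-5p	down	10651	5178	15	8	12.7	0.2	9.5	0.3	Dysregulated in DKD. Associated with fibrosis
hsa-miR-378a-3p	down	1445	740	10	5	9.9	0.3	3.1	1.6	Upregulation observed in biopsies from donors with glomerular diseases
hsa-miR-101-3p	down	971	483	0	0	8.6	1	1.4	0	Downregulated in kidneys from a mouse diabetic nephropathy model (STZ). Antifibrotic
hsa-miR-107	down	700	270	1	0.3	9	0.1	3.7	0.8	Downregulated in kidney biopsies from allograft dysfunction
hsa-miR-320b	down	466	262	2	1	8.2	0.3	2.4	1
hsa-miR-345-5p	down	236	121	0	0	7.2	0.4	1.4	0	Upregulated in urine from a chemical model of AKI in rats
hsa-miR-328-3p	down	203	88	0	0	7.1	0.3	1.4	0	Downregulated in proximal tubule cells that underwent ischemia/reperfusion
hsa-miR-204-3p	down	202	157	0	0	6.3	0.6	1.4	0	Upregulation protected podocytes exposed to high glucose from apoptosis
hsa-miR-7-5p	down	174	119	0	0	6.4	0.7	1.4	0	Downregulation protected proximal tubule cells from LPS in vitro
hsa-miR-197-3p	down	154	92	0	0	6	0.8	1.4	0	Downregulated in urine from donors with intermittent microalbuminuria
hsa-miR-20b-5p	down	151	80	0	0	6.7	0.6	1.4	0	Downregulated in kidneys and cell lines from mouse models of polycystic kidney disease
hsa-miR-148a-5p	down	133	60	0	0	6.3	0.3	1.4	0	Increased in urine from donors with persistent macroalbuminuria
hsa-miR-10a-3p	down	114	79	0	0	5.9	0.7	1.4	0	Downregulated in kidneys from a mouse model of AKI
hsa-miR-629-5p	down	109	81	0	0	5.5	0.5	1.4	0	Upregulated in kidney biopsies from donors with acute tubular necrosis
hsa-miR-92a-1-5p	down	101	59	0	0	5	0.4	1.4	0
hsa-miR-193b-3p	down	100	62	0	0	5.8	0.5	1.4	0	Upregulated in kidney from chronic kidney disease biopsies
hsa-miR-340-5p	down	99	36	0	0	6.2	0.3	1.4	0
hsa-miR-3065-5p	down	98	43	0	0	6.2	0.3	1.4	0	Upregulated in a mouse model of renal fibrosis
hsa-miR-106a-5p	down	92	50	0	0	5.8	0.4	1.4	0	Downregulation associated with podocyte injury induced by high glucose
hsa-miR-7704	down	87	37	0	0	5.8	0.2	1.4	0
hsa-miR-324-5p	down	74	42	0	0	5.5	0.3	1.4	0
hsa-miR-374b-5p	down	60	24	0	0	5.5	0.2	1.4	0	Downregulated in diabetic kidney biopsies
hsa-miR-99b-3p	down	59	19	0	0	5.6	0.3	1.4	0
hsa-miR-4728-3p	down	59	20	0	0	5.5	0.6	1.4	0
hsa-miR-132-3p	down	57	12	0	0	5.7	0.4	1.4	0	Upregulation increases fibrosis in mouse and in vitro
hsa-miR-361-5p	down	55	15	0	0	5.5	0.6	1.4	0
hsa-miR-664a-5p	down	54	15	0	0	5.6	0.3	1.4	0	Upregulated in uEV from donors with Idiopathic Membranous Nephropathy
hsa-miR-10a-5p	up	47380	33187	5272	2636	14.4	0.4	16.7	0.3	Downregulated in urine of individuals with AKI
hsa-miR-125a-5p	up	1017	399	103	51	9.3	0.7	12	0.2	Downregulated in urine from donors with membranous nephropathy
hsa-miR-92b-3p	up	864	413	58	29	9.1	0.2	11.4	0.3	Upregulated in urine from donors with persistent macroalbuminuria
hsa-miR-3960	up	77	44	15	7	4.8	1.1	9.4	0.5	Upregulated in kidney biopsies from donors with acute tubular necrosis
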