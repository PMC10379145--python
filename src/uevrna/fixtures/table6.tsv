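gene_id	role	isolation_workflows	dnase_treatment	technical	dkd_cohort1_t1d_men	dkd_cohort2_t1d_women	pca
HSPD1	candidate	0.23	0.13	0.15	0.14	0.16	0.12
SRSF3	candidate	0.21	0.13	0.17	0.15	0.18	0.16
VAPA	candidate	0.26	0.13	0.16	0.16	0.23	0.16
RAB1A	candidate	0.26	0.19	0.15	0.18	0.21	0.17
MORF4L1	candidate	0.22	0.13	0.17	0.21	0.16	0.16
PGK1	candidate	0.22	0.20	0.21	0.19	0.24	0.16
RHOA	candidate	0.17	0.16	0.19	0.15	0.22	0.16
UBE2D3	candidate	0.18	0.14	0.13	0.15	0.20	0.11
DAZAP2	candidate	0.26	0.19	0.19	0.20	0.17	0.16
UBC	candidate	0.19	0.16	0.16	0.20	0.38	0.11
ACTG1	candidate	0.13	0.19	0.14	0.15	0.25	0.08
GAPDH	common_reference	0.18	0.20	0.17	0.19	0.24	0.29
UPK1A	high_cv_comparison	0.70	0.36	0.59	0.63	0.49	0.49
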