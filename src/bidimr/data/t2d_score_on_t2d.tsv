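cohort	ancestry	n	outcome	scale	estimate	se	ci_low	ci_high	p	direction	subtotal	z
AIDHS/SDS	SOUTH_ASIAN	2675	T2D	OR	1.42		1.33	1.52	6.09E-13	+	0
SIKH REPLICATION	SOUTH_ASIAN	2197	T2D	OR	1.69		1.36	2.02	2.00E-03	+	0
IMS	SOUTH_ASIAN	848	T2D	OR	1.27		1.04	1.51	4.62E-02	+	0
SOUTH ASIAN META	SOUTH_ASIAN	5720	T2D	OR	1.42		1.34	1.50	1.33E-12	+	1	7.09
Twins UK	EUROPEAN	5335	T2D	OR	1.18		1.00	1.35	6.84E-02	+	0
1958 BC	EUROPEAN	5181	T2D	OR	1.30		1.13	1.46	1.81E-03	+	0
CCHS/CGPS/CIHDS	EUROPEAN	23029	T2D	OR	1.24		1.22	1.26	5.70E-15	+	0
UKHLS	EUROPEAN	8902	T2D	OR	1.18		1.09	1.26	1.53E-04	+	0
PREVEND	EUROPEAN	3649	T2D	OR	1.27		1.17	1.37	2.18E-06	+	0
Meta-Analysis		51816	T2D	OR	1.24		1.22	1.26	1.82E-32	+	1	11.86
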