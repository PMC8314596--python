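cohort	ancestry	n	outcome	scale	estimate	se	ci_low	ci_high	p	direction	subtotal	z
AIDHS/SDS	SOUTH_ASIAN	2388	T2D	OR	1.004		1.00	1.01	2.30E-02	+	0
SIKH REPLICATION	SOUTH_ASIAN	1846	T2D	OR	1.002		1.00	1.01	4.11E-01	+	0
SOUTH ASIAN META	SOUTH_ASIAN	4234	T2D	OR	1.003		1.00	1.01	2.90E-02	+	1	2.19
Twins UK	EUROPEAN	3679	T2D	OR	0.89		0.56	1.42	6.26E-01	-	0
1958 BC	EUROPEAN	4993	T2D	OR	1.00		0.99	1.05	7.92E-01	+	0
CCHS/CGPS/CIHDS	EUROPEAN	28372	T2D	OR	1.00		0.99	1.004	6.19E-01	+	0
PREVEND	EUROPEAN	3649	T2D	OR	1.00		0.98	1.03	6.79E-01	+	0
Meta-Analysis		44927	T2D	OR	1.002		1.001	1.005	1.20E-01	+	1	1.54
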