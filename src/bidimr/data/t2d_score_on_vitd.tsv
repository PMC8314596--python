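cohort	ancestry	n	outcome	scale	estimate	se	ci_low	ci_high	p	direction	subtotal	z
AIDHS/SDS	SOUTH_ASIAN	2675	VITD	BETA	-0.006	0.014			6.98E-01	-	0
SIKH REPLICATION	SOUTH_ASIAN	2197	VITD	BETA	-0.001	0.009			8.96E-01	-	0
SOUTH ASIAN META	SOUTH_ASIAN	4872	VITD	BETA	-0.003	0.008			7.45E-01	-	1	-0.367
Twins UK	EUROPEAN	5335	VITD	BETA	0.0004	0.001			7.07E-01	+	0
1958 BC	EUROPEAN	5181	VITD	BETA	0.1322	0.056			1.90E-02	+	0
CCHS/CGPS/CIHDS	EUROPEAN	11665	VITD	BETA	-0.0080	0.007			2.35E-01	-	0
PREVEND	EUROPEAN	3649	VITD	BETA	-0.0154	0.031			6.20E-01	-	0
Meta-Analysis		30702	VITD	BETA	-0.0002	0.0001			8.29E-01	-	1	-0.212
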