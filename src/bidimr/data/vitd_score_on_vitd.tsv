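cohort	ancestry	n	outcome	scale	estimate	se	ci_low	ci_high	p	direction	subtotal	z
AIDHS/SDS	SOUTH_ASIAN	2388	VITD	BETA	-0.042	0.012			2.70E-04	-	0
SIKH REPLICATION	SOUTH_ASIAN	1846	VITD	BETA	-0.025	0.009			4.00E-03	-	0
SOUTH ASIAN META	SOUTH_ASIAN	4234	VITD	BETA	-0.031	0.007			4.01E-06	-	1	-4.61
Twins UK	EUROPEAN	3679	VITD	BETA	-0.129	0.020			5.20E-11	-	0
1958 BC	EUROPEAN	4993	VITD	BETA	-0.035	0.005			4.20E-14	-	0
CCHS/CGPS/CIHDS	EUROPEAN	24581	VITD	BETA	-0.020	0.001			3.00E-39	-	0
PREVEND	EUROPEAN	3649	VITD	BETA	-0.021	0.002			3.70E-33	-	0
Meta-Analysis		41136	VITD	BETA	-0.021	0.001			7.92E-78	-	1	-18.68
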