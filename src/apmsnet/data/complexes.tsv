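complex	subunit
CCT	TCP1
CCT	CCT2
CCT	CCT3
CCT	CCT4
CCT	CCT5
CCT	CCT6A
CCT	CCT7
CCT	CCT8
prefoldin	PFDN1
prefoldin	PFDN2
prefoldin	PFDN4
prefoldin	PFDN5
prefoldin	PFDN6
prefoldin	VBP1
Sin3	SIN3A
Sin3	SAP18
Sin3	SAP30
Sin3	SAP130
Sin3	SUDS3
Sin3	ARID4B
Sin3	ING1
Sin3	RBBP4
Sin3	RBBP7
NuRD	CHD3
NuRD	CHD4
NuRD	MTA1
NuRD	MTA2
NuRD	MTA3
NuRD	GATAD2A
NuRD	GATAD2B
NuRD	MBD2
NuRD	MBD3
NuRD	RBBP4
NuRD	RBBP7
CoREST	RCOR1
CoREST	RCOR3
CoREST	KDM1A
CoREST	HMG20B
CoREST	PHF21A
MiDAC	DNTTIP1
MiDAC	ELMSAN1
MiDAC	TRERF1
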