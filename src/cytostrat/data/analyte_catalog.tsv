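analyte_id	current_name	historical_name	mw_daltons	class_label
CCL11	CCL11	Eotaxin	8360	chemokine
CCL2	CCL2	MCP1	8680	chemokine
CCL22	CCL22	MDC	8080	chemokine
CCL3	CCL3	MIP1a	7790	chemokine
CCL4	CCL4	MIP1B	7820	chemokine
CCL7	CCL7	MCP3	8960	chemokine
CD40LG	CD40LG	CD40Ligand	16300	tnf_family
CSF2	CSF2	GMCSF	14480	growth_factor
CSF3	CSF3	GCSF	18670	growth_factor
CX3CL1	CX3CL1	Fractalkine	8570	chemokine
CXCL1	CXCL1	GRO	7860	chemokine
CXCL10	CXCL10	IP10	8650	chemokine
EGF	EGF	EGF	6220	growth_factor
FGF2	FGF2	FGF2	17250	growth_factor
FLT3LG	FLT3LG	Flt3L	17560	growth_factor
IFNA2	IFNA2	IFNa2	19240	interferon
IFNG	IFNG	IFNG	16880	interferon
IL10	IL10	IL10	18640	interleukin
IL12B	IL12B	IL12B	34700	interleukin
IL12P70	IL12P70	IL12P70	57200	interleukin
IL13	IL13	IL13	12290	th2
IL15	IL15	IL15	12900	interleukin
IL17A	IL17A	IL17	15530	interleukin
IL1A	IL1A	IL1a	18050	interleukin
IL1B	IL1B	IL1B	17380	interleukin
IL1RN	IL1RN	IL1RA	17120	interleukin
IL2	IL2	IL2	15420	interleukin
IL2RA	IL2RA	IL2RA	24750	interleukin
IL3	IL3	IL3	15090	growth_factor
IL4	IL4	IL4	14960	th2
IL5	IL5	IL5	13150	th2
IL6	IL6	IL6	20900	interleukin
IL7	IL7	IL7	17390	interleukin
IL8	IL8	IL8	8380	chemokine
IL9	IL9	IL9	14150	th2
LTA	LTA	TNFB	18660	tnf_family
TGFA	TGFA	TGFa	5550	growth_factor
TNF	TNF	TNFA	17350	tnf_family
VEGFA	VEGFA	VEGF	19160	growth_factor
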