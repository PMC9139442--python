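drug	GRAY	CCLE	CTRPv2	FIMM	gCSI	GDSC1000	Caldas	confidence
AZD6244	0.72	0.42	0.42	0.28				High
Bortezomib	0.68		0.29	0.43	0.4	0.41	0.5	High
Docetaxel	0.76		0.8		0.48	0.43	0.43	High
Doxorubicin	0.78			0.28	0.6	-0.05		High
Erlotinib	0.76	0.41	0.31	-0.09	0.57	0.3	-0.13	High
Gefitinib	0.74		0.37	0.22		0.33	0.47	High
Gemcitabine	0.75		0.35		0.48	0.19	0.3	High
GSK1059615	0.73		0.49					High
GSK1120212	0.78		0.54				0.19	High
GSK461364	0.78		0.72					High
Irinotecan	0.8	0.13		-0.13	0.57			High
Lapatinib	0.77	0.68	0.54	0.5	0.34	0.26	0.9	High
MG-132	0.76		0.47			0.31		High
Nutlin-3	0.74	0.22	0.42					High
Paclitaxel	0.77	0.36	0.61	0.37	0.42	0.12	-0.1	High
Panobinostat	0.78	0.76	0.6	0.72				High
Rapamycin	0.7		0.44		-0.17	-0.05		High
Topotecan	0.76	0.6	0.36	0.15				High
VX-680	0.69		0.52			0.21		High
ZM-447439	0.7					0.28	0.46	High
5-FU	0.77		0.31					Medium
BIBW2992	0.79		0.4	0.39			0.37	Medium
Cisplatin	0.79					0.37	0.29	Medium
Crizotinib	0.75	0.21	0.36	-0.04	0.39	0.03		Medium
Etoposide	0.75		0.38			0.21		Medium
GSK2126458	0.73					0.33		Medium
Methotrexate	0.74		0.18	0.09		0.39		Medium
Temsirolimus	0.72			0.4		0.1		Medium
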